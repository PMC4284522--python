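"""AGP v2.1 serialization of scaffold layouts, plus scaffold FASTA assembly.

Components are the bins' source spans; consecutive bins that are not
contiguous neighbours on their source sequence are separated by a 100-bp
gap of type "scaffold" with evidence "proximity_ligation".
"""

from __future__ import annotations

from typing import Sequence

from .genome import Bin, GenomeStructure, PlacedBin, Scaffold

__all__ = ["write_agp", "read_agp", "scaffold_sequences", "GAP_LENGTH"]

GAP_LENGTH = 100


def _source_adjacent(a: Bin, pa: PlacedBin, b: Bin, pb: PlacedBin) -> bool:
    """True when two consecutive placements are contiguous on their source."""
    if a.source_name != b.source_name or pa.orientation != pb.orientation:
        return False
    if pa.orientation == 1:
        return a.source_end == b.source_start
    return b.source_end == a.source_start


def write_agp(structure: GenomeStructure, path) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for sc in structure.scaffolds:
            pos = 1
            part = 1
            prev: tuple[Bin, PlacedBin] | None = None
            for p in sc.placed:
                b = structure.bins[p.bin_id]
                if prev is not None and not _source_adjacent(prev[0], prev[1], b, p):
                    fh.write(
                        f"{sc.name}\t{pos}\t{pos + GAP_LENGTH - 1}\t{part}\tU\t"
                        f"{GAP_LENGTH}\tscaffold\tyes\tproximity_ligation\n"
                    )
                    pos += GAP_LENGTH
                    part += 1
                end = pos + b.length_bp - 1
                ori = "+" if p.orientation == 1 else "-"
                fh.write(
                    f"{sc.name}\t{pos}\t{end}\t{part}\tW\t{b.source_name}\t"
                    f"{b.source_start + 1}\t{b.source_end}\t{ori}\n"
                )
                pos = end + 1
                part += 1
                prev = (b, p)


def read_agp(path, bins: Sequence[Bin]) -> GenomeStructure:
    """Rebuild a layout from AGP written by :func:`write_agp`.

    Components are matched back to bins by (source_name, source span); copy
    indices are reassigned in encounter order per bin, which reproduces the
    canonical numbering of duplicate-free layouts.
    """
    by_span = {(b.source_name, b.source_start, b.source_end): b.bin_id for b in bins}
    counters = [0] * len(bins)
    chains: dict[str, list[PlacedBin]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if f[4] in ("N", "U"):
                continue
            name = f[0]
            key = (f[5], int(f[6]) - 1, int(f[7]))
            if key not in by_span:
                raise ValueError(f"AGP component {key} matches no bin")
            bin_id = by_span[key]
            ori = 1 if f[8] in ("+", "?", "0", "na") else -1
            if not bins[bin_id].orientable:
                ori = 1
            if name not in chains:
                chains[name] = []
                order.append(name)
            chains[name].append(PlacedBin(bin_id, ori, counters[bin_id]))
            counters[bin_id] += 1
    scaffolds = [Scaffold(name, tuple(chains[name])) for name in order]
    placed = {p.bin_id for sc in scaffolds for p in sc.placed}
    unplaced = set(range(len(bins))) - placed
    return GenomeStructure(bins, scaffolds, unplaced)


def scaffold_sequences(
    structure: GenomeStructure, sources: dict[str, str]
) -> dict[str, str]:
    """Assemble scaffold sequences from source sequences, joining bins with
    100-N gaps where they are not source-contiguous."""
    from Bio.Seq import Seq

    out: dict[str, str] = {}
    for sc in structure.scaffolds:
        parts: list[str] = []
        prev: tuple[Bin, PlacedBin] | None = None
        for p in sc.placed:
            b = structure.bins[p.bin_id]
            if prev is not None and not _source_adjacent(prev[0], prev[1], b, p):
                parts.append("N" * GAP_LENGTH)
            seq = sources[b.source_name][b.source_start : b.source_end]
            if p.orientation == -1:
                seq = str(Seq(seq).reverse_complement())
            parts.append(seq)
            prev = (b, p)
        out[sc.name] = "".join(parts)
    return out
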