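"""Synthetic contact data: simulate matrices from a known structure, scramble
genomes, and inject misassembly signatures.

The simulator draws independent Poisson counts around the same power-law /
plateau intensities the likelihood uses, scaled so the expected total equals
the requested read number.  It emulates the validation conditions of the
method: a 16-chromosome budding-yeast-like genome, random scrambles
(permutation plus orientation flips), and the classic misassembly signatures
— reciprocal translocations, inversions, segmental duplications, and
collapsed duplications whose rows carry roughly twice the contacts of
ordinary bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import Bin, GenomeStructure, PlacedBin, Scaffold, _rc
from .model import ContactMatrix, NuisanceParams, _intensity_full

__all__ = [
    "SimulationSpec",
    "simulate_contacts",
    "scramble",
    "inject_rearrangement",
    "yeast_like_genome",
    "four_chromosome_genome",
    "DEFAULT_PARAMS",
]

# Study-condition defaults: b=-1.5 with a 100-kb plateau, loosely yeast-like.
DEFAULT_PARAMS = NuisanceParams(b=-1.5, s0=1.0e5, pt=1.0e-9)

# Chromosome length ratios (bp) used by the genome factories.
_YEAST_CHR_BP = (
    230218, 813184, 316620, 1531933, 576874, 270161, 1090940, 562643,
    439888, 745751, 666816, 1078177, 924431, 784333, 1091291, 948066,
)
# hg19 chromosomes 7, 17, 19 and 22.
_HUMAN4_CHR_BP = (159138663, 81195210, 59128983, 51304566)


@dataclass(frozen=True)
class SimulationSpec:
    """Inputs of one simulation: truth structure, model parameters, depth, seed."""

    truth: GenomeStructure
    params: NuisanceParams = DEFAULT_PARAMS
    n_contacts: int = 10_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contacts <= 0:
            raise ValueError("n_contacts must be positive")


def _ratio_genome(
    chr_bp: tuple[int, ...],
    names: list[str],
    total_bp: int,
    n_bins: int,
    rf_per_bp: float,
) -> GenomeStructure:
    total_ref = sum(chr_bp)
    bins: list[Bin] = []
    chains: list[list[tuple[int, int]]] = []
    for name, ref_len in zip(names, chr_bp):
        chrom_len = int(round(total_bp * ref_len / total_ref))
        k = max(2, int(round(n_bins * ref_len / total_ref)))
        base = chrom_len // k
        chain = []
        start = 0
        for j in range(k):
            L = base if j < k - 1 else chrom_len - base * (k - 1)
            n_rf = max(2, int(round(L * rf_per_bp)))
            bins.append(
                Bin(
                    bin_id=len(bins),
                    length_bp=L,
                    n_rf=n_rf,
                    source_name=name,
                    source_start=start,
                )
            )
            chain.append((bins[-1].bin_id, 1))
            start += L
        chains.append(chain)
    return GenomeStructure.from_arrangement(bins, chains, names=names)


def yeast_like_genome(
    total_bp: int | None = None, n_bins: int = 160, bin_bp: int = 30_000
) -> GenomeStructure:
    """16 chromosomes with S. cerevisiae length ratios.

    Unless ``total_bp`` is given, the genome scales with ``n_bins`` at
    ~30-kb orientable bins, preserving the regime where the contact decay
    spans a few bins before hitting the plateau.
    """
    if total_bp is None:
        total_bp = bin_bp * n_bins
    names = [f"chr{i + 1:02d}" for i in range(16)]
    return _ratio_genome(_YEAST_CHR_BP, names, total_bp, n_bins, rf_per_bp=1 / 400)


def four_chromosome_genome(
    total_bp: int | None = None, n_bins: int = 200, bin_bp: int = 30_000
) -> GenomeStructure:
    """Four chromosomes with hg19 7/17/19/22 length ratios, scaled down."""
    if total_bp is None:
        total_bp = bin_bp * n_bins
    names = ["chr7", "chr17", "chr19", "chr22"]
    return _ratio_genome(_HUMAN4_CHR_BP, names, total_bp, n_bins, rf_per_bp=1 / 400)


def simulate_contacts(spec: SimulationSpec) -> ContactMatrix:
    """Poisson contact matrix with expected total ``n_contacts``.

    Counts are drawn pair-wise Poisson, equivalent in distribution to
    read-by-read multinomial sampling at a fixed expected total.
    Deterministic given the spec seed.
    """
    data = ContactMatrix.empty(spec.truth.bins)
    I = _intensity_full(data, spec.truth, spec.params)
    raw = data._L2 * I
    denom = (raw.sum() + np.trace(raw)) / 2.0
    lam = raw * (spec.n_contacts / denom)
    rng = np.random.default_rng(spec.seed)
    upper = np.triu(rng.poisson(np.triu(lam)).astype(np.float64))
    counts = upper + np.triu(upper, 1).T
    return ContactMatrix(spec.truth.bins, counts)


def scramble(
    truth: GenomeStructure,
    seed: int | np.random.Generator = 0,
    n_scaffolds: int | None = None,
) -> GenomeStructure:
    """Random permutation of all placements into ``n_scaffolds`` scaffolds with
    i.i.d. random orientations; the bin multiset is conserved.  Defaults to
    the truth's scaffold count."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    placements = [(p.bin_id) for sc in truth.scaffolds for p in sc.placed]
    order = rng.permutation(len(placements))
    shuffled = [placements[i] for i in order]
    oris = rng.integers(0, 2, size=len(shuffled)) * 2 - 1
    if n_scaffolds is None:
        n_scaffolds = len(truth.scaffolds)
    n_scaffolds = min(n_scaffolds, len(shuffled))
    cuts = np.sort(rng.choice(np.arange(1, len(shuffled)), n_scaffolds - 1, replace=False))
    bounds = [0, *cuts.tolist(), len(shuffled)]
    chains = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        chains.append([(shuffled[i], int(oris[i])) for i in range(a, b)])
    out = GenomeStructure.from_arrangement(truth.bins, chains)
    return GenomeStructure(out.bins, out.scaffolds, truth.unplaced)


def inject_rearrangement(
    truth: GenomeStructure,
    kind: str,
    span: tuple[str, int, int],
    seed: int = 0,
    target: tuple[str, int] | None = None,
) -> tuple[GenomeStructure, dict]:
    """Plant one structural variant into ``truth``.

    Parameters
    ----------
    kind:
        ``"translocation"`` (reciprocal arm exchange at the span start and the
        target position), ``"inversion"`` (reverse order and orientation of
        the span), ``"segmental_duplication"`` (copy the span at the target),
        or ``"collapsed_duplication"`` (extra copies of the span placed at the
        target: simulating reads from this truth while initialising from the
        original single-copy structure produces the ~2x marginal signature).
    span:
        ``(scaffold_name, start_rank, end_rank)`` half-open bin ranks.
    target:
        ``(scaffold_name, rank)`` insertion/cut point for moves that need one;
        drawn at random (seeded) if omitted.

    Returns the rearranged structure and a breakpoint report.
    """
    rng = np.random.default_rng(seed)
    by_name = {sc.name: i for i, sc in enumerate(truth.scaffolds)}
    sname, lo, hi = span
    if sname not in by_name:
        raise ValueError(f"unknown scaffold {sname!r}")
    si = by_name[sname]
    src = truth.scaffolds[si].placed
    if not (0 <= lo < hi <= len(src)):
        raise ValueError("span crosses scaffold ends")
    scaffolds = list(truth.scaffolds)
    report = {"kind": kind, "span": span}

    if target is None:
        others = [sc.name for sc in truth.scaffolds if sc.name != sname] or [sname]
        tname = others[int(rng.integers(len(others)))]
        trank = int(rng.integers(len(truth.scaffolds[by_name[tname]].placed) + 1))
        target = (tname, trank)
    report["target"] = target

    if kind == "inversion":
        seg = _rc(truth.bins, src[lo:hi])
        scaffolds[si] = Scaffold(sname, src[:lo] + seg + src[hi:])
        return truth._rebuild(scaffolds, truth.unplaced), report

    tname, trank = target
    ti = by_name[tname]
    tgt = scaffolds[ti].placed

    if kind == "translocation":
        if ti == si:
            raise ValueError("translocation needs two distinct scaffolds")
        la, ra = src[:lo], src[lo:]
        lb, rb = tgt[:trank], tgt[trank:]
        scaffolds[si] = Scaffold(sname, la + rb) if la + rb else None
        scaffolds[ti] = Scaffold(tname, lb + ra) if lb + ra else None
        report["arms"] = {"kept": [sname, tname], "exchanged_at": [lo, trank]}
        return truth._rebuild(
            [sc for sc in scaffolds if sc is not None], truth.unplaced
        ), report

    if kind in ("segmental_duplication", "collapsed_duplication"):
        counters = list(truth._next_copy)
        copies = []
        for p in src[lo:hi]:
            copies.append(PlacedBin(p.bin_id, p.orientation, counters[p.bin_id]))
            counters[p.bin_id] += 1
        if ti == si and trank >= lo and trank <= hi:
            raise ValueError("duplication target inside the span")
        tgt = scaffolds[ti].placed
        scaffolds[ti] = Scaffold(tname, tgt[:trank] + tuple(copies) + tgt[trank:])
        report["duplicated_bins"] = [p.bin_id for p in src[lo:hi]]
        return truth._rebuild(scaffolds, truth.unplaced, tuple(counters)), report

    raise ValueError(f"unknown rearrangement kind {kind!r}")
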