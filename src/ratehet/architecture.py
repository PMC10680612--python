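"""Chromosome layout and per-window rate maps.

Builds a Drosophila-like genic architecture — tandem gene + intergenic
units, each gene with alternating exons and introns — annotates every
site with a functional class, and constructs per-window mutation and
recombination rate maps that are either fixed or drawn from a uniform
distribution and rescaled so the chromosome-wide mean matches the fixed
rate exactly.

Coordinates are 0-based half-open throughout; exon masks are written as
3-column BED, rate maps as TSV (window_start, window_end, rate).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

# site class codes (kept uint8-compatible for the simulator)
EXON_SEL = 0
EXON_SYN = 1
INTRON = 2
INTERGENIC = 3

CLASS_NAMES = {EXON_SEL: "exon_sel", EXON_SYN: "exon_syn",
               INTRON: "intron", INTERGENIC: "intergenic"}
CLASS_CODES = {v: k for k, v in CLASS_NAMES.items()}

#: conversion from cM/Mb to crossover probability per bp per generation
CM_PER_MB_TO_PER_BP = 1e-8


@dataclass(frozen=True)
class GenicStructure:
    """Repeating gene + intergenic unit sizes.

    The default values are genome-wide averages for D. melanogaster
    protein-coding genes: 127 genes of four 588-bp exons and three
    563-bp introns, separated by 3,811-bp intergenic spacers, giving a
    997,204-bp chromosome.
    """

    n_genes: int = 127
    exons_per_gene: int = 4
    exon_len: int = 588
    introns_per_gene: int = 3
    intron_len: int = 563
    intergenic_len: int = 3811

    def __post_init__(self) -> None:
        for name in ("n_genes", "exons_per_gene", "exon_len",
                     "introns_per_gene", "intron_len", "intergenic_len"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.exons_per_gene > 0 and self.introns_per_gene > 0:
            if self.exons_per_gene != self.introns_per_gene + 1:
                raise ValueError("exons must alternate with introns: "
                                 "exons_per_gene == introns_per_gene + 1")

    @property
    def gene_len(self) -> int:
        return (self.exons_per_gene * self.exon_len
                + self.introns_per_gene * self.intron_len)

    @property
    def unit_len(self) -> int:
        return self.gene_len + self.intergenic_len

    @property
    def total_length(self) -> int:
        return self.n_genes * self.unit_len


@dataclass
class SiteClassMap:
    """Per-site functional annotation of a chromosome.

    ``intervals`` is a run-length encoding: (start, end, class_code)
    triples that tile [0, total_length) exactly.
    """

    total_length: int
    intervals: list[tuple[int, int, int]]
    _classes: np.ndarray | None = field(default=None, repr=False)

    def class_array(self) -> np.ndarray:
        """Dense uint8 array of site-class codes, one entry per site."""
        if self._classes is None:
            arr = np.empty(self.total_length, dtype=np.uint8)
            for s, e, c in self.intervals:
                arr[s:e] = c
            self._classes = arr
        return self._classes

    def class_census(self) -> dict[str, int]:
        arr = self.class_array()
        return {CLASS_NAMES[c]: int(np.sum(arr == c)) for c in CLASS_NAMES}

    def truncate(self, length: int) -> "SiteClassMap":
        """Clip the map to the first ``length`` bp."""
        if not 0 < length <= self.total_length:
            raise ValueError("length out of range")
        ivals = [(s, min(e, length), c) for s, e, c in self.intervals
                 if s < length]
        return SiteClassMap(length, ivals)


def build_layout(structure: GenicStructure) -> SiteClassMap:
    """Lay out the chromosome and annotate site classes.

    Each gene is exon, intron, ..., exon followed by an intergenic
    spacer. Within every exon, each third site (1-based positions 3, 6,
    9, ...) is synonymous (``exon_syn``); the remaining two thirds are
    directly selected (``exon_sel``).
    """
    L = structure.total_length
    if L == 0:
        raise ValueError("zero-length chromosome")
    intervals: list[tuple[int, int, int]] = []
    pos = 0
    for _ in range(structure.n_genes):
        for e in range(structure.exons_per_gene):
            exon_start = pos
            # synonymous phase: offsets 2, 5, 8, ... within the exon
            for off in range(structure.exon_len):
                cls = EXON_SYN if off % 3 == 2 else EXON_SEL
                intervals.append((exon_start + off, exon_start + off + 1, cls))
            pos += structure.exon_len
            if e < structure.introns_per_gene:
                intervals.append((pos, pos + structure.intron_len, INTRON))
                pos += structure.intron_len
        if structure.intergenic_len:
            intervals.append((pos, pos + structure.intergenic_len, INTERGENIC))
            pos += structure.intergenic_len
    assert pos == L
    return SiteClassMap(L, _merge_runs(intervals))


def _merge_runs(intervals):
    merged = []
    for s, e, c in intervals:
        if merged and merged[-1][2] == c and merged[-1][1] == s:
            merged[-1] = (merged[-1][0], e, c)
        else:
            merged.append((s, e, c))
    return merged


def exon_mask(layout: SiteClassMap) -> list[tuple[int, int]]:
    """BED-convention intervals covering all exonic (sel + syn) sites."""
    mask = []
    for s, e, c in layout.intervals:
        if c in (EXON_SEL, EXON_SYN):
            if mask and mask[-1][1] == s:
                mask[-1] = (mask[-1][0], e)
            else:
                mask.append((s, e))
    return mask


@dataclass
class RateMap:
    """Per-window rates tiling a chromosome.

    ``rates`` holds one value per ``window_len`` window (the final
    window may be shorter). Mutation rates are per site per generation;
    recombination rates are crossover probabilities per bp per
    generation.
    """

    kind: str  # "mutation" | "recombination"
    window_len: int
    rates: np.ndarray
    total_length: int

    def __post_init__(self) -> None:
        if self.kind not in ("mutation", "recombination"):
            raise ValueError("kind must be 'mutation' or 'recombination'")
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")
        n_windows = -(-self.total_length // self.window_len)
        if len(self.rates) != n_windows:
            raise ValueError("rates length does not tile the chromosome")

    @property
    def window_lengths(self) -> np.ndarray:
        n = len(self.rates)
        lens = np.full(n, self.window_len, dtype=np.int64)
        lens[-1] = self.total_length - (n - 1) * self.window_len
        return lens

    def mean_rate(self) -> float:
        """Length-weighted mean rate per bp."""
        lens = self.window_lengths
        return float(np.dot(self.rates, lens) / lens.sum())

    def per_site(self) -> np.ndarray:
        """Dense per-site rate array."""
        return np.repeat(self.rates, self.window_lengths)

    def truncate(self, length: int) -> "RateMap":
        n = -(-length // self.window_len)
        return RateMap(self.kind, self.window_len, self.rates[:n].copy(),
                       length)


def make_rate_map(kind: str, total_length: int, fixed_rate: float,
                  variable: bool = False, a: float | None = None,
                  b: float | None = None, window_len: int = 1000,
                  seed: int | None = None,
                  rng: np.random.Generator | None = None) -> RateMap:
    """Build a fixed or uniform-variable rate map.

    For ``variable`` maps, per-window rates are drawn from Uniform(a, b)
    and then multiplied by ``fixed_rate / empirical mean`` so that the
    length-weighted chromosome average equals ``fixed_rate`` exactly
    (individual windows may end up slightly outside [a, b]).

    Recombination inputs are taken in cM/Mb and converted to crossover
    probability per bp per generation (x 1e-8).
    """
    if fixed_rate <= 0:
        raise ValueError("fixed_rate must be > 0")
    n_windows = -(-total_length // window_len)
    if variable:
        if a is None or b is None:
            raise ValueError("variable maps need uniform limits a, b")
        if not 0 <= a <= b:
            raise ValueError("need 0 <= a <= b")
        if rng is None:
            rng = np.random.default_rng(seed)
        draws = rng.uniform(a, b, size=n_windows)
        lens = np.full(n_windows, window_len, dtype=np.int64)
        lens[-1] = total_length - (n_windows - 1) * window_len
        emp_mean = np.dot(draws, lens) / lens.sum()
        rates = draws * (fixed_rate / emp_mean)
    else:
        rates = np.full(n_windows, fixed_rate, dtype=float)
    if kind == "recombination":
        rates = rates * CM_PER_MB_TO_PER_BP
    return RateMap(kind, window_len, rates, total_length)


def rescale_rate_map(rate_map: RateMap, Q: float) -> RateMap:
    """Multiply all rates by the rescaling factor Q.

    Rescaled recombination rates implying a per-adjacent-site crossover
    probability above 0.5 are rejected rather than capped.
    """
    if Q < 1:
        raise ValueError("Q must be >= 1")
    rates = rate_map.rates * Q
    if rate_map.kind == "recombination" and np.any(rates > 0.5):
        raise ValueError("rescaled crossover probability exceeds 0.5/bp")
    return replace(rate_map, rates=rates)


# ---------------------------------------------------------------------------
# on-disk formats

def write_bed(intervals, path, chrom: str = "chr1") -> None:
    with open(path, "w") as fh:
        for s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path) -> list[tuple[int, int]]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            out.append((int(parts[1]), int(parts[2])))
    return out


def write_rate_map(rate_map: RateMap, path) -> None:
    lens = rate_map.window_lengths
    starts = np.concatenate([[0], np.cumsum(lens)[:-1]])
    with open(path, "w") as fh:
        fh.write(f"# kind={rate_map.kind} window_len={rate_map.window_len} "
                 f"total_length={rate_map.total_length}\n")
        fh.write("window_start\twindow_end\trate\n")
        for s, ln, r in zip(starts, lens, rate_map.rates):
            fh.write(f"{s}\t{s + ln}\t{r:.12e}\n")


def read_rate_map(path) -> RateMap:
    with open(path) as fh:
        header = fh.readline().strip().lstrip("# ")
        meta = dict(kv.split("=") for kv in header.split())
        fh.readline()  # column names
        rates = [float(line.split("\t")[2]) for line in fh if line.strip()]
    return RateMap(meta["kind"], int(meta["window_len"]),
                   np.array(rates), int(meta["total_length"]))
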