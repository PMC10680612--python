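"""Site frequency spectra and windowed summary statistics.

An :class:`SFS` is an unfolded (or folded) single-population spectrum:
``counts[i]`` is the number of polymorphic sites whose derived allele
appears in i of n sampled chromosomes. Bins 0 and n are bookkeeping
only and are masked in all likelihoods downstream.

Windowed summaries (pi, Watterson's theta, Tajima's D, S) follow the
standard definitions over sliding windows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .architecture import CLASS_CODES
from .simulate import ReplicateResult

__all__ = ["SFS", "WindowStats", "sfs_from_replicates", "pool_sfs", "fold",
           "write_fs", "read_fs", "window_summaries", "tajimas_d_constants",
           "pi_from_haplotypes"]


@dataclass
class SFS:
    n: int
    counts: np.ndarray  # length n+1 (unfolded) or floor(n/2)+1 (folded)
    span_bp: float = np.nan
    masked: bool = False
    class_filter: tuple[str, ...] | None = None
    folded: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        expect = (self.n // 2 + 1) if self.folded else (self.n + 1)
        if len(self.counts) != expect:
            raise ValueError("counts length does not match sample size")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def segregating(self) -> float:
        """Total polymorphic count (excludes bins 0 and n)."""
        if self.folded:
            return float(self.counts[1:].sum())
        return float(self.counts[1:-1].sum())

    def __add__(self, other: "SFS") -> "SFS":
        if self.n != other.n or self.folded != other.folded:
            raise ValueError("cannot pool spectra with different shapes")
        return replace(self, counts=self.counts + other.counts,
                       span_bp=self.span_bp + other.span_bp)

    def pi_per_site(self) -> float:
        """Pairwise diversity per bp via the SFS route."""
        if self.folded:
            raise ValueError("need an unfolded spectrum")
        i = np.arange(self.n + 1)
        w = 2.0 * i * (self.n - i) / (self.n * (self.n - 1))
        return float(np.dot(w, self.counts) / self.span_bp)


def _interval_mask(intervals, L: int) -> np.ndarray:
    m = np.zeros(L, dtype=bool)
    for s, e in intervals:
        m[s:e] = True
    return m


def sfs_from_replicates(reps, mask=None, class_filter=None,
                        layout=None) -> SFS:
    """Tally derived-allele counts into an unfolded SFS.

    ``mask`` is a list of (start, end) intervals to exclude (e.g. the
    exon mask); ``class_filter`` restricts to the named site classes
    (requires ``layout`` to compute the monitored span). span_bp is the
    per-replicate monitored length times the number of replicates.
    """
    if isinstance(reps, ReplicateResult):
        reps = [reps]
    if not reps:
        raise ValueError("no replicates")
    n = reps[0].n
    if any(r.n != n for r in reps):
        raise ValueError("replicates have inconsistent sample sizes")
    L = reps[0].total_length
    keep_site = np.ones(L, dtype=bool)
    if mask is not None:
        keep_site &= ~_interval_mask(mask, L)
    codes = None
    if class_filter is not None:
        codes = {CLASS_CODES[c] if isinstance(c, str) else int(c)
                 for c in class_filter}
        if layout is None:
            raise ValueError("class_filter requires the site-class layout")
        cls_arr = layout.class_array()
        keep_site &= np.isin(cls_arr, sorted(codes))
    span_per_rep = int(keep_site.sum())
    counts = np.zeros(n + 1)
    for r in reps:
        use = keep_site[r.positions]
        dac = r.haplotypes[:, use].sum(axis=0)
        counts += np.bincount(dac, minlength=n + 1)
    names = None if class_filter is None else tuple(
        sorted(c if isinstance(c, str) else str(c) for c in class_filter))
    return SFS(n, counts, span_bp=float(span_per_rep * len(reps)),
               masked=mask is not None, class_filter=names)


def pool_sfs(spectra) -> SFS:
    """Pool spectra additively (order-invariant)."""
    spectra = list(spectra)
    out = spectra[0]
    for s in spectra[1:]:
        out = out + s
    return out


def fold(sfs: SFS) -> SFS:
    """Minor-allele spectrum over bins 0..floor(n/2)."""
    if sfs.folded:
        return sfs
    n = sfs.n
    half = n // 2
    counts = np.zeros(half + 1)
    for i in range(n + 1):
        counts[min(i, n - i)] += sfs.counts[i]
    return replace(sfs, counts=counts, folded=True)


# ---------------------------------------------------------------------------
# dadi-style .fs text format

def write_fs(sfs: SFS, path=None) -> str:
    """Single-population dadi-style .fs: header "<len> unfolded|folded",
    the entries, and a 0/1 mask line (1 = masked) masking bins 0 and n."""
    kind = "folded" if sfs.folded else "unfolded"
    entries = " ".join(f"{c:.12g}" for c in sfs.counts)
    m = np.zeros(len(sfs.counts), dtype=int)
    m[0] = 1
    if not sfs.folded:
        m[-1] = 1
    text = (f"{len(sfs.counts)} {kind}\n{entries}\n"
            + " ".join(map(str, m)) + "\n")
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_fs(source) -> SFS:
    """Parse an .fs written by :func:`write_fs` (or a path to one)."""
    text = source
    if "\n" not in str(source):
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    length_s, kind = lines[0].split()[:2]
    counts = np.array([float(x) for x in lines[1].split()])
    if len(counts) != int(length_s):
        raise ValueError("corrupt .fs: entry count mismatch")
    folded = kind == "folded"
    n = (len(counts) - 1) * (2 if folded else 1)
    return SFS(n, counts, folded=folded)


# ---------------------------------------------------------------------------
# windowed summary statistics

@dataclass
class WindowStats:
    start: int
    end: int
    S: int
    pi: float          # per bp
    theta_w: float     # per bp
    tajimas_d: float   # nan when undefined (S == 0)
    truncated: bool = False

    @property
    def d_defined(self) -> bool:
        return np.isfinite(self.tajimas_d)


def tajimas_d_constants(n: int) -> dict[str, float]:
    """The standard a1,a2,b1,b2,c1,c2,e1,e2 variance constants."""
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i ** 2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def pi_from_haplotypes(hap: np.ndarray) -> float:
    """Total (not per-bp) pairwise diversity of a 0/1 haplotype matrix."""
    n = hap.shape[0]
    p = hap.mean(axis=0)
    return float(np.sum(2.0 * p * (1 - p)) * n / (n - 1))


def window_summaries(rep: ReplicateResult, window_len: int = 5000,
                     step: int = 2500) -> list[WindowStats]:
    """pi, Watterson's theta, Tajima's D and S in sliding windows."""
    L = rep.total_length
    n = rep.n
    const = tajimas_d_constants(n)
    a1, e1, e2 = const["a1"], const["e1"], const["e2"]
    p = rep.haplotypes.mean(axis=0)
    site_pi = 2.0 * p * (1 - p) * n / (n - 1)
    out = []
    start = 0
    while start < L:
        end = min(start + window_len, L)
        lo, hi = np.searchsorted(rep.positions, [start, end])
        S = int(hi - lo)
        pi_tot = float(site_pi[lo:hi].sum())
        wlen = end - start
        if S > 0:
            D_num = pi_tot - S / a1
            D_den = np.sqrt(e1 * S + e2 * S * (S - 1))
            D = D_num / D_den if D_den > 0 else np.nan
        else:
            D = np.nan
        out.append(WindowStats(start, end, S, pi_tot / wlen,
                               S / (a1 * wlen), D,
                               truncated=end - start < window_len))
        start += step
    return out
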