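"""Diploid Wright-Fisher forward simulation with linked selection.

The simulator evolves a single panmictic diploid population over a
genic chromosome: new mutations arise under a per-window mutation rate
map, crossovers under a recombination rate map, and mutations falling
on directly selected exonic sites draw a selection coefficient from a
discrete four-class DFE over 2N*s (semi-dominant, h = 0.5; genotype
fitnesses 1, 1 - s/2, 1 - s, multiplicative across sites). Populations
start monomorphic, burn in for 16N generations, pass through optional
instantaneous size changes, and are sampled as haplotypes.

All parameters can be rescaled by a factor Q (N -> N/Q; mu, r, s -> xQ)
which preserves the population-scaled quantities 2Nmu, 2Nr and 2Ns
while shortening runtimes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels as K
from .architecture import EXON_SEL, RateMap, SiteClassMap

__all__ = [
    "DiscreteDFE", "DemographyPlan", "ReplicateResult", "SimulationError",
    "GAMMA_CLASS_BOUNDS", "draw_selection_coefficient", "apply_rescaling",
    "simulate_replicate",
]

#: boundaries of the four 2N*s classes (effectively neutral, weakly,
#: moderately, strongly deleterious); the upper bound of the strong
#: class is the DFE's gamma_max
GAMMA_CLASS_BOUNDS = (0.0, 1.0, 10.0, 100.0)


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class DiscreteDFE:
    """Discrete DFE: probabilities of the four 2N_ancestral*s classes.

    Class k covers 2Ns in [b_k, b_{k+1}) with boundaries 0, 1, 10, 100
    and ``gamma_max``; within a class, s is uniform. ``gamma_max=None``
    defaults to 2*N_ancestral at simulation time (i.e. s up to 1, the
    homozygous-lethal cap).
    """

    f0: float
    f1: float
    f2: float
    f3: float
    gamma_max: float | None = None

    def __post_init__(self) -> None:
        f = self.f
        if np.any(np.asarray(f) < 0):
            raise ValueError("class probabilities must be >= 0")
        if abs(sum(f) - 1.0) > 1e-9:
            raise ValueError("class probabilities must sum to 1")

    @property
    def f(self) -> tuple[float, float, float, float]:
        return (self.f0, self.f1, self.f2, self.f3)

    def resolved_gamma_max(self, N_ancestral: int) -> float:
        return 2.0 * N_ancestral if self.gamma_max is None else self.gamma_max


@dataclass(frozen=True)
class DemographyPlan:
    """Single-population history: burn-in plus piecewise-constant epochs.

    ``epochs`` are (relative size nu, duration in units of the epoch's
    own N) applied after the 16N (by default) burn-in; sampling happens
    at the end of the final epoch. N_ancestral is given at the same
    scale as the rate maps and is divided by Q at simulation time.
    """

    N_ancestral: float
    epochs: tuple[tuple[float, float], ...] = ()
    burn_in_N: float = 16.0
    sample_n: int = 100

    def __post_init__(self) -> None:
        if self.N_ancestral <= 0 or self.burn_in_N <= 0:
            raise ValueError("sizes and burn-in must be > 0")
        for nu, dur in self.epochs:
            if nu <= 0 or dur <= 0:
                raise ValueError("epoch sizes and durations must be > 0")
        if self.sample_n < 2 or self.sample_n % 2:
            raise ValueError("sample_n must be an even count >= 2")

    @classmethod
    def equilibrium(cls, N_ancestral: float, sample_n: int = 100):
        return cls(N_ancestral, (), sample_n=sample_n)

    @classmethod
    def size_change(cls, N_ancestral: float, nu: float,
                    duration_N: float = 1.0, sample_n: int = 100):
        """Instantaneous change to nu*N_ancestral, then ``duration_N``
        N_current generations before sampling (default 1N)."""
        return cls(N_ancestral, ((nu, duration_N),), sample_n=sample_n)


@dataclass
class ReplicateResult:
    """Sampled output of one forward replicate.

    ``haplotypes`` is an n x S binary matrix (1 = derived) over the
    segregating sites ``positions`` (sorted, unique); ``site_class``
    and ``s`` give each site's annotation and selection coefficient
    (0 for neutral classes).
    """

    positions: np.ndarray
    haplotypes: np.ndarray
    site_class: np.ndarray
    s: np.ndarray
    total_length: int
    seed: int | None
    Q: float
    n_fixed: int = 0

    @property
    def n(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def S(self) -> int:
        return self.haplotypes.shape[1]

    def __post_init__(self) -> None:
        if len(self.positions) != self.haplotypes.shape[1]:
            raise ValueError("positions do not match haplotype columns")


def draw_selection_coefficient(dfe: DiscreteDFE, N_ancestral: int,
                               rng: np.random.Generator,
                               size: int | None = None):
    """Draw s for new directly selected mutations.

    Picks a 2Ns class with probabilities (f0..f3), then s uniform over
    the class's s-interval [b_k/(2N), b_{k+1}/(2N)).
    """
    gmax = dfe.resolved_gamma_max(N_ancestral)
    bounds = np.array(list(GAMMA_CLASS_BOUNDS) + [gmax]) / (2.0 * N_ancestral)
    m = 1 if size is None else size
    k = rng.choice(4, size=m, p=np.asarray(dfe.f))
    s = rng.uniform(bounds[k], bounds[k + 1])
    return float(s[0]) if size is None else s


@dataclass(frozen=True)
class RescaledParams:
    N: int
    mut_map: RateMap
    rec_map: RateMap
    dfe: DiscreteDFE | None
    Q: float


def apply_rescaling(N: float, mut_map: RateMap, rec_map: RateMap,
                    dfe: DiscreteDFE | None, Q: float) -> RescaledParams:
    """Divide N by Q and multiply mu, r (and implicitly s) by Q.

    The population-scaled products 2Nmu, 2Nr and 2Ns are invariant.
    Rejects rescalings that would push any selection coefficient above
    1 or the population below 10 diploids.
    """
    from .architecture import rescale_rate_map

    if Q < 1:
        raise ValueError("Q must be >= 1")
    N_r = int(round(N / Q))
    if N_r < 10:
        raise ValueError("rescaled N below 10 diploids")
    if dfe is not None:
        gmax = dfe.resolved_gamma_max(N_r)
        if gmax / (2.0 * N_r) > 1.0 + 1e-12:
            raise ValueError("rescaled s exceeds 1 for the strongest class")
    return RescaledParams(N_r, rescale_rate_map(mut_map, Q),
                          rescale_rate_map(rec_map, Q), dfe, Q)


# ---------------------------------------------------------------------------
# internal population state

class _Population:
    """Mutable state of the evolving population (see _kernels)."""

    def __init__(self, L, class_arr, mut_map, rec_map, dfe, N0, N_anc,
                 rows_cap, rng, purge_interval=25):
        self.L = L
        self.class_arr = class_arr
        self.dfe = dfe
        self.N = N0
        self.N_anc = N_anc
        self.rows_cap = rows_cap
        self.rng = rng
        self.purge_interval = purge_interval
        self.gen = 0
        self.n_fixed = 0

        mu_site = mut_map.per_site()
        self.U_tot = float(mu_site.sum())
        self.mut_cum = np.cumsum(mut_map.rates * mut_map.window_lengths)
        self.mut_starts = np.concatenate(
            [[0], np.cumsum(mut_map.window_lengths)[:-1]]).astype(np.int64)
        self.mut_lens = mut_map.window_lengths

        self.R_tot = float(np.dot(rec_map.rates, rec_map.window_lengths))
        self.rec_cum = np.cumsum(rec_map.rates * rec_map.window_lengths)
        self.rec_starts = np.concatenate(
            [[0], np.cumsum(rec_map.window_lengths)[:-1]]).astype(np.int64)
        self.rec_lens = rec_map.window_lengths

        # neutral packed store
        self.Sn = 0
        self.n_pos = np.empty(0, dtype=np.int64)
        self.n_cls = np.empty(0, dtype=np.uint8)
        self.W = 1
        self.packed = np.zeros((rows_cap, self.W), dtype=np.uint64)
        self.packed_buf = np.zeros((rows_cap, self.W), dtype=np.uint64)

        # selected dense store
        self.Ss = 0
        self.s_pos = np.empty(0, dtype=np.int64)
        self.s_val = np.empty(0, dtype=np.float64)
        self.sel = np.zeros((rows_cap, 0), dtype=np.uint8)
        self.sel_buf = np.zeros((rows_cap, 0), dtype=np.uint8)
        self.lhet = np.empty(0)
        self.lhom = np.empty(0)

        # newborn sparse store
        self.nb_pos = np.empty(0, dtype=np.int64)
        self.nb_s = np.empty(0, dtype=np.float64)
        self.nb_cls = np.empty(0, dtype=np.uint8)
        self.nb_lhet = np.empty(0, dtype=np.float64)
        self.nb_lhom = np.empty(0, dtype=np.float64)
        self.car_off = np.zeros(1, dtype=np.int64)
        self.car_hap = np.empty(0, dtype=np.int64)
        self.car_cap = max(4096, int(16 * self.U_tot * 2 * rows_cap))

        self.occupied = np.zeros(L, dtype=np.uint8)  # 0 free, 1 seg, 2 fixed
        self.stamp = np.empty(rows_cap // 2 + 1, dtype=np.int64)
        self.has_selection = dfe is not None
        # scratch for transmit_newborns
        self._cnt_buf = np.zeros(rows_cap // 2 + 3, dtype=np.int64)
        self._order_buf = np.empty(rows_cap, dtype=np.int64)
        self._hap_buf = np.empty(self.car_cap, dtype=np.int64)

    # -- per-generation step -------------------------------------------------

    def step(self, N_next: int) -> None:
        rng = self.rng
        n_par = self.N
        n_gam = 2 * N_next

        selecting = self.has_selection and (
            self.Ss > 0 or len(self.nb_pos) > 0)
        if selecting:
            logw = np.zeros(n_par)
            if self.Ss:
                K.fitness_selected(self.sel, n_par, self.Ss,
                                   self.lhet, self.lhom, logw)
            if len(self.nb_pos):
                self.stamp[:n_par] = -1
                K.fitness_newborn(self.car_off, self.car_hap, self.nb_lhet,
                                  self.nb_lhom, len(self.nb_pos),
                                  self.stamp, logw)
            w = np.exp(logw - logw.max())
            cw = np.cumsum(w)
            if cw[-1] <= 0 or not np.isfinite(cw[-1]):
                raise SimulationError("population fitness collapsed")
            parent_idx = np.searchsorted(
                cw, rng.random(n_gam) * cw[-1]).astype(np.int64)
        else:
            parent_idx = rng.integers(0, n_par, n_gam, dtype=np.int64)

        nx = rng.poisson(self.R_tot, n_gam)
        xoff = np.zeros(n_gam + 1, dtype=np.int64)
        np.cumsum(nx, out=xoff[1:])
        xflat = self._sample_positions(self.rec_cum, self.rec_starts,
                                       self.rec_lens, int(xoff[-1]))
        np.maximum(xflat, 1, out=xflat)  # breakpoints split [0,L) non-trivially
        start_hap = rng.integers(0, 2, n_gam, dtype=np.int64)

        K.recombine(self.packed, self.packed_buf, self.n_pos, self.Sn,
                    self.sel, self.sel_buf, self.s_pos, self.Ss,
                    parent_idx, xflat, xoff, start_hap, n_gam)
        self.packed, self.packed_buf = self.packed_buf, self.packed
        self.sel, self.sel_buf = self.sel_buf, self.sel

        nb_n = len(self.nb_pos)
        if nb_n:
            while True:
                new_off = np.zeros(nb_n + 1, dtype=np.int64)
                m = K.transmit_newborns(self.nb_pos, nb_n, self.car_off,
                                        self.car_hap, parent_idx, n_gam,
                                        n_par, xflat, xoff, start_hap,
                                        new_off, self._hap_buf, self.car_cap,
                                        self._cnt_buf, self._order_buf)
                if m >= 0:
                    break
                self.car_cap *= 2
                self._hap_buf = np.empty(self.car_cap, dtype=np.int64)
            self.car_off = new_off
            self.car_hap = self._hap_buf[:m].copy()
            self._compact_newborns()

        self.N = N_next
        self._mutate(n_gam)
        self.gen += 1
        if self.gen % self.purge_interval == 0:
            self.purge()

    def _sample_positions(self, cum, starts, lens, n):
        if n == 0:
            return np.empty(0, dtype=np.int64)
        u = self.rng.random(n) * cum[-1]
        win = np.searchsorted(cum, u)
        off = (self.rng.random(n) * lens[win]).astype(np.int64)
        return starts[win] + off

    def _mutate(self, n_gam: int) -> None:
        rng = self.rng
        n_mut = rng.poisson(self.U_tot * n_gam)
        if n_mut == 0:
            return
        sites = np.empty(n_mut, dtype=np.int64)
        filled = 0
        while filled < n_mut:
            cand = self._sample_positions(self.mut_cum, self.mut_starts,
                                          self.mut_lens, n_mut - filled)
            # sequential acceptance so intra-batch collisions redraw too
            filled = K.accept_new_sites(cand, self.occupied, sites, filled)
        gam = rng.integers(0, n_gam, n_mut, dtype=np.int64)
        cls = self.class_arr[sites]
        s = np.zeros(n_mut)
        if self.has_selection:
            is_sel = cls == EXON_SEL
            if is_sel.any():
                s[is_sel] = draw_selection_coefficient(
                    self.dfe, self.N_anc, rng, size=int(is_sel.sum()))
        self.nb_pos = np.concatenate([self.nb_pos, sites])
        self.nb_s = np.concatenate([self.nb_s, s])
        self.nb_cls = np.concatenate([self.nb_cls, cls])
        with np.errstate(divide="ignore"):
            self.nb_lhet = np.concatenate(
                [self.nb_lhet, np.log1p(-0.5 * s)])
            self.nb_lhom = np.concatenate([self.nb_lhom, np.log1p(-s)])
        self.car_off = np.concatenate(
            [self.car_off,
             self.car_off[-1] + 1 + np.arange(n_mut, dtype=np.int64)])
        self.car_hap = np.concatenate([self.car_hap, gam])

    def _compact_newborns(self) -> None:
        """Drop newborn columns whose carrier list emptied (lost)."""
        counts = np.diff(self.car_off)
        lost = counts == 0
        if not lost.any():
            return
        self.occupied[self.nb_pos[lost]] = 0
        keep = ~lost
        self.nb_pos = self.nb_pos[keep]
        self.nb_s = self.nb_s[keep]
        self.nb_cls = self.nb_cls[keep]
        self.nb_lhet = self.nb_lhet[keep]
        self.nb_lhom = self.nb_lhom[keep]
        self.car_off = np.concatenate(
            [[0], np.cumsum(counts[keep])]).astype(np.int64)

    # -- purge / graduate ----------------------------------------------------

    def _bits(self, n_rows):
        if self.Sn == 0:
            return np.empty((n_rows, 0), dtype=np.uint8)
        byte_view = self.packed[:n_rows].view(np.uint8)
        return np.unpackbits(byte_view, axis=1,
                             bitorder="little")[:, :self.Sn]

    def _pack(self, bits):
        """Pack a (rows, Sn) bit matrix into fresh packed buffers."""
        packed = np.zeros((self.rows_cap, self.W), dtype=np.uint64)
        if bits.size:
            pb = np.packbits(bits, axis=1, bitorder="little")
            buf = np.zeros((bits.shape[0], self.W * 8), dtype=np.uint8)
            buf[:, :pb.shape[1]] = pb
            packed[:bits.shape[0]] = buf.view(np.uint64)
        return packed

    def purge(self) -> None:
        """Remove fixed/lost columns and graduate newborn columns.

        Fixed and lost columns are harmless between purges (they do not
        affect relative fitness or transmission), so this runs on a
        long interval; it is the only place columns are re-sorted.
        """
        n2 = 2 * self.N
        bits = self._bits(n2)
        ncnt = bits.sum(axis=0, dtype=np.int64) if self.Sn else \
            np.empty(0, dtype=np.int64)
        scnt = self.sel[:n2, :self.Ss].sum(axis=0, dtype=np.int64)
        nbcnt = np.diff(self.car_off)

        for pos_arr, cnt in ((self.n_pos, ncnt), (self.s_pos, scnt),
                             (self.nb_pos, nbcnt)):
            fixed = cnt == n2
            self.n_fixed += int(fixed.sum())
            self.occupied[pos_arr[fixed]] = 2
            self.occupied[pos_arr[cnt == 0]] = 0

        nb_idx = np.flatnonzero((nbcnt > 0) & (nbcnt < n2))
        nb_to_sel = self.nb_s[nb_idx] > 0

        def rebuild(keep, old_pos, grads, grad_pos):
            """Order old kept + graduating newborn columns by position;
            graduates get index -1 (a zero column scattered later)."""
            old_idx = np.flatnonzero(keep)
            src = np.concatenate(
                [old_idx, np.full(len(grads), -1, dtype=np.int64)])
            pos = np.concatenate([old_pos[old_idx], grad_pos])
            order = np.argsort(pos, kind="stable")
            return pos[order], src[order], order

        def scatter_newborns(mat, src_sorted, order, grads):
            cols = np.flatnonzero(src_sorted == -1)
            grad_of_col = grads[order[cols] - (len(src_sorted) - len(grads))]
            for col, c in zip(cols, grad_of_col):
                mat[self.car_hap[self.car_off[c]:self.car_off[c + 1]],
                    col] = 1

        # neutral store: one gather pass over an extended bit matrix
        # whose last column is all-zero (target of the -1 indices)
        nkeep = (ncnt > 0) & (ncnt < n2)
        grads_n = nb_idx[~nb_to_sel]
        npos, nsrc, norder = rebuild(nkeep, self.n_pos, grads_n,
                                     self.nb_pos[grads_n])
        ext = np.concatenate([bits, np.zeros((n2, 1), np.uint8)], axis=1)
        new_nbits = np.ascontiguousarray(ext[:, nsrc])
        scatter_newborns(new_nbits, nsrc, norder, grads_n)
        self.n_cls = np.concatenate(
            [self.n_cls[nkeep], self.nb_cls[grads_n]])[norder]
        self.n_pos = npos
        self.Sn = len(self.n_pos)
        self.W = max(1, -(-int(self.Sn + 64) // 64))
        self.packed = self._pack(new_nbits)
        self.packed_buf = np.zeros_like(self.packed)

        # selected store
        skeep = (scnt > 0) & (scnt < n2)
        grads_s = nb_idx[nb_to_sel]
        spos, ssrc, sorder = rebuild(skeep, self.s_pos, grads_s,
                                     self.nb_pos[grads_s])
        ext = np.concatenate([self.sel[:n2, :self.Ss],
                              np.zeros((n2, 1), np.uint8)], axis=1)
        new_sbits = np.ascontiguousarray(ext[:, ssrc])
        scatter_newborns(new_sbits, ssrc, sorder, grads_s)
        self.s_val = np.concatenate(
            [self.s_val[skeep], self.nb_s[grads_s]])[sorder]
        self.s_pos = spos
        self.Ss = len(self.s_pos)
        self.sel = np.zeros((self.rows_cap, self.Ss), dtype=np.uint8)
        self.sel[:n2] = new_sbits
        self.sel_buf = np.zeros_like(self.sel)
        with np.errstate(divide="ignore"):
            self.lhet = np.log1p(-0.5 * self.s_val)
            self.lhom = np.log1p(-self.s_val)

        # reset newborn store
        self.nb_pos = np.empty(0, dtype=np.int64)
        self.nb_s = np.empty(0, dtype=np.float64)
        self.nb_cls = np.empty(0, dtype=np.uint8)
        self.nb_lhet = np.empty(0)
        self.nb_lhom = np.empty(0)
        self.car_off = np.zeros(1, dtype=np.int64)
        self.car_hap = np.empty(0, dtype=np.int64)

    def sample(self, sample_n: int, seed, Q) -> ReplicateResult:
        """Sample ``sample_n`` haplotypes as both haplotypes of
        sample_n/2 distinct individuals; drop non-segregating columns."""
        if sample_n > 2 * self.N:
            raise SimulationError("sample larger than the population")
        self.purge()
        inds = self.rng.choice(self.N, sample_n // 2, replace=False)
        rows = np.empty(sample_n, dtype=np.int64)
        rows[0::2] = 2 * inds
        rows[1::2] = 2 * inds + 1
        bits = self._bits(2 * self.N)[rows]
        selbits = self.sel[rows, :self.Ss]
        positions = np.concatenate([self.n_pos, self.s_pos])
        cls = np.concatenate([self.n_cls,
                              np.full(self.Ss, EXON_SEL, dtype=np.uint8)])
        svals = np.concatenate([np.zeros(self.Sn), self.s_val])
        hap = np.concatenate([bits, selbits], axis=1)
        order = np.argsort(positions, kind="stable")
        positions, cls, svals, hap = (positions[order], cls[order],
                                      svals[order], hap[:, order])
        dac = hap.sum(axis=0)
        seg = (dac > 0) & (dac < sample_n)
        return ReplicateResult(positions[seg], np.ascontiguousarray(hap[:, seg]),
                               cls[seg], svals[seg], self.L, seed, Q,
                               n_fixed=self.n_fixed)


# ---------------------------------------------------------------------------

def simulate_replicate(layout: SiteClassMap, mut_map: RateMap,
                       rec_map: RateMap, dfe: DiscreteDFE | None,
                       demography: DemographyPlan, Q: float = 1.0,
                       seed: int | None = None,
                       purge_interval: int = 25) -> ReplicateResult:
    """Run one forward replicate and sample haplotypes.

    ``dfe=None`` simulates a strictly neutral chromosome (all s = 0).
    Inputs (N, rate maps) are given at their natural scale and rescaled
    by Q internally.
    """
    if not (layout.total_length == mut_map.total_length
            == rec_map.total_length):
        raise ValueError("layout and rate maps disagree on length")
    params = apply_rescaling(demography.N_ancestral, mut_map, rec_map,
                             dfe, Q)
    N0 = params.N
    rng = np.random.default_rng(seed)

    # epoch schedule in generations at the rescaled scale
    sizes = [N0]
    durations = [int(round(demography.burn_in_N * N0))]
    for nu, dur_N in demography.epochs:
        Ne = max(10, int(round(nu * N0)))
        sizes.append(Ne)
        durations.append(int(round(dur_N * Ne)))
    rows_cap = 2 * max(sizes)

    pop = _Population(layout.total_length, layout.class_array(),
                      params.mut_map, params.rec_map, params.dfe,
                      N0, N0, rows_cap, rng, purge_interval)
    for Ne, T in zip(sizes, durations):
        for _ in range(T):
            # the first generation of an epoch produces Ne children
            pop.step(Ne)
    return pop.sample(demography.sample_n, seed, Q)
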