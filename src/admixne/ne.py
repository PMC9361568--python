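"""Recent effective population size from an IBD segment length spectrum.

Model
-----
For a haplotype pair, the probability that a locus coalesces exactly g
generations ago under piecewise-constant diploid sizes N_g is

    q_g = (1 / (2 N_g)) * prod_{k=g_min}^{g-1} (1 - 1 / (2 N_k)).

Conditional on coalescence at g, IBD segments of genetic length u (Morgans)
around a locus arise at density lambda(u | g) = L (2g)^2 exp(-2 g u), with
L the analysed genome length in Morgans (interior approximation, no
chromosome-end correction).  The expected count in a length bin [a, b) is

    E[a, b) = n_pairs * sum_g q_g * L * 2g * (exp(-2ga) - exp(-2gb)),

with the coalescence mass beyond the fitted grid closed by a constant
ancient epoch at N_{g_max} (or truncated).  ``fit_ne`` minimizes the Poisson
negative log-likelihood of observed bin counts over log N_g with a smoothness
penalty on successive log-size differences; ``bootstrap_ne`` resamples
chromosome chunks for percentile confidence bounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize

__all__ = [
    "NeTrajectory",
    "IBDLengthSpectrum",
    "default_bin_edges",
    "spectrum_from_lengths",
    "expected_spectrum",
    "fit_ne",
    "bootstrap_ne",
    "exclude_related",
]


@dataclass
class NeTrajectory:
    """Piecewise-constant diploid effective size over a generation grid."""

    generations: np.ndarray  # ascending, generations before present
    ne: np.ndarray
    lwr: np.ndarray | None = None
    upr: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.generations = np.asarray(self.generations, dtype=float)
        self.ne = np.asarray(self.ne, dtype=float)
        if np.any(np.diff(self.generations) <= 0):
            raise ValueError("generation grid must be strictly ascending")
        if self.generations.shape != self.ne.shape:
            raise ValueError("generations/ne length mismatch")
        if np.any(self.ne <= 0):
            raise ValueError("effective sizes must be positive")
        for b in (self.lwr, self.upr):
            if b is not None and np.asarray(b).shape != self.ne.shape:
                raise ValueError("confidence bounds must align with the grid")
        if self.lwr is not None and self.upr is not None:
            if np.any(np.asarray(self.lwr) > self.ne + 1e-9) or np.any(
                self.ne > np.asarray(self.upr) + 1e-9
            ):
                raise ValueError("need lwr <= ne <= upr")

    def at(self, g) -> np.ndarray:
        """Size at generation(s) g (piecewise constant, last value held)."""
        idx = np.clip(np.searchsorted(self.generations, np.asarray(g, dtype=float), side="right") - 1, 0, len(self.ne) - 1)
        return self.ne[idx]

    # -------------------------------------------------------------- table I/O
    def to_table(self) -> pd.DataFrame:
        df = pd.DataFrame({"GEN": self.generations, "NE": self.ne})
        if self.lwr is not None:
            df["LWR"] = self.lwr
        if self.upr is not None:
            df["UPR"] = self.upr
        return df

    def write(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False, float_format="%.6f")

    @classmethod
    def read(cls, path) -> "NeTrajectory":
        df = pd.read_csv(path, sep=r"\s+")
        cols = {c.upper(): c for c in df.columns}
        if "GEN" not in cols or "NE" not in cols:
            raise ValueError("expected GEN and NE columns")
        return cls(
            generations=df[cols["GEN"]].to_numpy(float),
            ne=df[cols["NE"]].to_numpy(float),
            lwr=df[cols["LWR"]].to_numpy(float) if "LWR" in cols else None,
            upr=df[cols["UPR"]].to_numpy(float) if "UPR" in cols else None,
        )


@dataclass
class IBDLengthSpectrum:
    """Binned IBD segment lengths with the exposure needed by the model."""

    bin_edges: np.ndarray  # cM, ascending; last edge may be inf (open tail)
    counts: np.ndarray
    n_pairs: float  # haplotype pairs contributing
    genome_cm: float  # total genetic length analysed
    chrom_lengths_cm: np.ndarray | None = None  # per-chromosome lengths (cM)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.counts) != len(self.bin_edges) - 1:
            raise ValueError("counts/bin_edges mismatch")
        if np.any(self.counts < 0):
            raise ValueError("negative counts")
        if self.n_pairs <= 0 or self.genome_cm <= 0:
            raise ValueError("n_pairs and genome_cm must be positive")
        if self.chrom_lengths_cm is not None:
            self.chrom_lengths_cm = np.asarray(self.chrom_lengths_cm, dtype=float)
            if not np.isclose(self.chrom_lengths_cm.sum(), self.genome_cm):
                raise ValueError("chromosome lengths must sum to genome_cm")


def default_bin_edges(min_cm: float = 3.0, max_cm: float = 20.0, width_cm: float = 0.5) -> np.ndarray:
    """Bins of ``width_cm`` from ``min_cm`` to ``max_cm`` plus one open tail."""
    return np.concatenate([np.arange(min_cm, max_cm + width_cm / 2, width_cm), [np.inf]])


def spectrum_from_lengths(
    lengths_cm,
    n_pairs: float,
    genome_cm: float,
    bin_edges: np.ndarray | None = None,
    chrom_lengths_cm=None,
) -> IBDLengthSpectrum:
    if bin_edges is None:
        bin_edges = default_bin_edges()
    lengths_cm = np.asarray(lengths_cm, dtype=float)
    counts, _ = np.histogram(lengths_cm, bins=np.nan_to_num(bin_edges, posinf=1e12))
    return IBDLengthSpectrum(
        bin_edges=bin_edges, counts=counts, n_pairs=n_pairs, genome_cm=genome_cm,
        chrom_lengths_cm=chrom_lengths_cm,
    )


def exclude_related(segments: pd.DataFrame, genome_cm: float, max_fraction: float = 0.10) -> tuple[pd.DataFrame, int]:
    """Drop haplotype pairs whose total IBD exceeds ``max_fraction`` of the
    genome (close relatives: their very recent coalescences lie below the
    fitted grid and would flood the long-length tail).  Returns the filtered
    table and the number of pairs removed."""
    if segments.empty:
        return segments.copy(), 0
    key = ["sample_a", "hap_a", "sample_b", "hap_b"]
    tot = segments.groupby(key)["length_cm"].sum()
    bad = set(tot[tot > max_fraction * genome_cm].index)
    if not bad:
        return segments.copy(), 0
    mask = [tuple(t) not in bad for t in segments[key].itertuples(index=False)]
    return segments[mask].reset_index(drop=True), len(bad)


# ----------------------------------------------------------------- the model


def _coalescence_mass(
    ne_grid: np.ndarray, generations: np.ndarray, g_cap: int, tail: str
) -> tuple[np.ndarray, np.ndarray]:
    """(g values, q_g) for g from the grid start up to ``g_cap``.

    Generations between grid knots take the size of the preceding knot;
    beyond the last knot the size is held constant (``tail='constant'``) or
    coalescence stops (``tail='truncate'``)."""
    g_min = int(generations[0])
    g_max = int(generations[-1])
    g = np.arange(g_min, g_cap + 1)
    idx = np.clip(np.searchsorted(generations, g, side="right") - 1, 0, len(ne_grid) - 1)
    n_of_g = ne_grid[idx]
    if tail == "truncate":
        n_of_g = np.where(g > g_max, np.inf, n_of_g)
    elif tail != "constant":
        raise ValueError("tail must be 'constant' or 'truncate'")
    s = 1.0 / (2.0 * n_of_g)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - s)[:-1]])
    return g, s * surv


def _bin_integrals(g: np.ndarray, edges_cm: np.ndarray) -> np.ndarray:
    """Interior approximation: I[g, b] = 2g (exp(-2 g a_b) - exp(-2 g b_b)),
    edges in Morgans, to be multiplied by L = genome Morgans."""
    a = edges_cm[:-1] / 100.0
    b = edges_cm[1:] / 100.0
    ga = np.exp(-2.0 * np.outer(g, a))
    gb = np.where(np.isinf(b), 0.0, np.exp(-2.0 * np.outer(g, np.nan_to_num(b, posinf=1.0))))
    return 2.0 * g[:, None] * (ga - gb)


def _bin_integrals_finite(g: np.ndarray, edges_cm: np.ndarray, chrom_cm: np.ndarray) -> np.ndarray:
    """Exact finite-chromosome bin integrals, summed over chromosomes.

    For a chromosome of C Morgans and TMRCA g, the segment-length density is
    (2g)^2 (C - u) e^(-2gu) for interior segments plus 2 * 2g e^(-2gu) for the
    two end segments (u < C), plus an atom e^(-2gC) at u = C (no breakpoint).
    The total over [0, C] is 2gC + 1 segments, as it must be.  Unlike the
    interior approximation these integrals already include the genome length,
    so they multiply n_pairs only.
    """
    a = edges_cm[:-1] / 100.0
    b = np.nan_to_num(edges_cm[1:] / 100.0, posinf=np.inf)
    gam = 2.0 * g[:, None]
    out = np.zeros((len(g), len(a)))
    for C_cm in chrom_cm:
        C = C_cm / 100.0
        aa = np.minimum(a, C)[None, :]
        bb = np.minimum(b, C)[None, :]

        def anti(u):  # antiderivative of gam^2 (C - u) e^(-gam u)
            return np.exp(-gam * u) * (1.0 - gam * (C - u))

        interior = anti(bb) - anti(aa)
        ends = 2.0 * (np.exp(-gam * aa) - np.exp(-gam * bb))
        atom = np.where((a[None, :] <= C) & (C < b[None, :]), np.exp(-gam * C), 0.0)
        out += interior + ends + atom
    return out


def _g_cap(generations: np.ndarray, edges_cm: np.ndarray) -> int:
    a_min_m = edges_cm[0] / 100.0
    return int(max(generations[-1] * 4, min(5000, np.ceil(23.0 / (2.0 * a_min_m)))))


def expected_spectrum(
    traj: NeTrajectory,
    n_pairs: float,
    genome_cm: float,
    bin_edges: np.ndarray,
    tail: str = "constant",
    g_cap: int | None = None,
    chrom_lengths_cm=None,
) -> np.ndarray:
    """Expected IBD segment counts per length bin under the trajectory.

    With ``chrom_lengths_cm`` the exact finite-chromosome correction is used
    (end segments shorten the spectrum noticeably when segment lengths are
    not tiny relative to the chromosome); otherwise the interior
    approximation over ``genome_cm``.
    """
    bin_edges = np.asarray(bin_edges, dtype=float)
    if len(bin_edges) < 2:
        raise ValueError("need at least one bin")
    if np.any(traj.ne <= 0):
        raise ValueError("effective sizes must be positive")
    if g_cap is None:
        g_cap = _g_cap(traj.generations, bin_edges)
    g, q = _coalescence_mass(traj.ne, traj.generations, g_cap, tail)
    if chrom_lengths_cm is not None:
        integrals = _bin_integrals_finite(g, bin_edges, np.asarray(chrom_lengths_cm, float))
        return n_pairs * (q @ integrals)
    integrals = _bin_integrals(g, bin_edges)
    L = genome_cm / 100.0
    return n_pairs * L * (q @ integrals)


# ------------------------------------------------------------------- fitting


def _nll_and_grad(
    theta: np.ndarray,
    generations: np.ndarray,
    counts: np.ndarray,
    n_pairs: float,
    L_morgans: float,
    integrals: np.ndarray,
    g: np.ndarray,
    smooth_penalty: float,
    tail: str,
) -> tuple[float, np.ndarray]:
    ne = np.exp(theta)
    idx = np.clip(np.searchsorted(generations, g, side="right") - 1, 0, len(ne) - 1)
    n_of_g = ne[idx]
    if tail == "truncate":
        beyond = g > generations[-1]
        s = np.where(beyond, 0.0, 1.0 / (2.0 * n_of_g))
    else:
        s = 1.0 / (2.0 * n_of_g)
    surv = np.concatenate([[1.0], np.cumprod(1.0 - s)[:-1]])
    q = s * surv
    mu = n_pairs * L_morgans * (q @ integrals)
    mu = np.maximum(mu, 1e-300)
    nll = float(np.sum(mu - counts * np.log(mu)))

    # dl(q_g)/dtheta_j = -[own rate maps to j] + s_j/(1-s_j) * #{k<g: map(k)=j}
    k = len(theta)
    own = np.zeros((len(g), k))
    nprev = np.zeros((len(g), k))
    if tail == "truncate":
        active = ~ (g > generations[-1])
    else:
        active = np.ones(len(g), dtype=bool)
    for j in range(k):
        mine = (idx == j) & active
        own[mine, j] = 1.0
        # number of generations before g whose rate is s_j
        nprev[:, j] = np.cumsum(np.concatenate([[0.0], mine[:-1].astype(float)]))
    sj = 1.0 / (2.0 * ne)
    ratio = sj / (1.0 - sj)
    dlogq = -own + nprev * ratio[None, :]
    w = 1.0 - counts / mu  # d nll / d mu
    # d mu_b / d theta_j = C L sum_g q_g dlogq_gj I_gb
    grad = np.einsum("b,gj,g,gb->j", w, dlogq, q, integrals) * n_pairs * L_morgans

    d = np.diff(theta)
    nll += smooth_penalty * float(np.sum(d * d))
    gpen = np.zeros(k)
    gpen[:-1] -= 2.0 * smooth_penalty * d
    gpen[1:] += 2.0 * smooth_penalty * d
    return nll, grad + gpen


def _flat_start(spectrum: IBDLengthSpectrum, generations: np.ndarray, tail: str) -> float:
    """Constant-size method-of-moments start: match the total expected count."""
    total = float(spectrum.counts.sum())
    if total == 0:
        raise ValueError("insufficient IBD: the spectrum is all zero")

    def f(logn):
        traj = NeTrajectory(generations=generations, ne=np.full(len(generations), np.exp(logn)))
        return float(
            expected_spectrum(
                traj, spectrum.n_pairs, spectrum.genome_cm, spectrum.bin_edges, tail,
                chrom_lengths_cm=spectrum.chrom_lengths_cm,
            ).sum()
        ) - total

    lo, hi = np.log(2.0), np.log(1e8)
    if f(lo) < 0:  # even tiny sizes cannot produce this many segments
        return lo
    if f(hi) > 0:
        return hi
    return brentq(f, lo, hi, xtol=1e-10)


def fit_ne(
    spectrum: IBDLengthSpectrum,
    grid: np.ndarray | None = None,
    smooth_penalty: float = 0.02,
    tail: str = "constant",
    ftol: float = 1e-6,
    max_iter: int = 500,
) -> NeTrajectory:
    """Fit a piecewise-constant N_e trajectory to an IBD length spectrum.

    Minimizes the Poisson negative log-likelihood of the bin counts under
    :func:`expected_spectrum` over log N_g, plus a smoothness penalty
    ``smooth_penalty * (total segment count) * sum (log N_{g+1} - log N_g)^2``
    (scaling the penalty with the data keeps the fit invariant when counts
    and n_pairs are scaled jointly, and keeps the effective smoothing level
    independent of study size).  Deterministic: the optimizer starts from a
    flat method-of-moments trajectory.
    """
    if grid is None:
        grid = np.arange(4, 51)
    grid = np.asarray(grid, dtype=float)
    if np.count_nonzero(spectrum.counts) < 1:
        raise ValueError("insufficient IBD: the spectrum is all zero")
    g_cap = _g_cap(grid, spectrum.bin_edges)
    g = np.arange(int(grid[0]), g_cap + 1)
    if spectrum.chrom_lengths_cm is not None:
        integrals = _bin_integrals_finite(g, spectrum.bin_edges, spectrum.chrom_lengths_cm)
        L_eff = 1.0
    else:
        integrals = _bin_integrals(g, spectrum.bin_edges)
        L_eff = spectrum.genome_cm / 100.0
    theta0 = np.full(len(grid), _flat_start(spectrum, grid, tail))
    total = float(spectrum.counts.sum())

    def objective(theta):
        # per-segment normalization makes the fit exactly invariant under
        # joint scaling of counts and n_pairs (same optimizer path)
        f, gr = _nll_and_grad(
            theta, grid, spectrum.counts, spectrum.n_pairs, L_eff,
            integrals, g, smooth_penalty * total, tail,
        )
        return f / total, gr / total

    res = minimize(
        objective,
        theta0,
        jac=True,
        method="L-BFGS-B",
        bounds=[(np.log(2.0), np.log(1e8))] * len(grid),
        options={"ftol": ftol, "maxiter": max_iter},
    )
    if not res.success:
        raise RuntimeError(f"N_e optimization did not converge: {res.message} (nit={res.nit})")
    return NeTrajectory(generations=grid, ne=np.exp(res.x))


def bootstrap_ne(
    chunks: list[pd.DataFrame],
    chunk_cm: list[float],
    n_pairs: float,
    n_boot: int,
    seed,
    grid: np.ndarray | None = None,
    bin_edges: np.ndarray | None = None,
    smooth_penalty: float = 200.0,
    tail: str = "constant",
) -> NeTrajectory:
    """Chunk bootstrap over chromosomes (or chromosome chunks).

    The point estimate uses all chunks; ``n_boot`` resamples with replacement
    give percentile 2.5/97.5 bounds per generation.  Deterministic given seed.
    """
    if len(chunks) < 2:
        raise ValueError("need at least 2 chunks to bootstrap")
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    if bin_edges is None:
        bin_edges = default_bin_edges()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    def fit_over(idx: list[int]) -> NeTrajectory:
        lengths = np.concatenate(
            [chunks[i]["length_cm"].to_numpy() for i in idx if len(chunks[i])]
            or [np.empty(0)]
        )
        genome = float(sum(chunk_cm[i] for i in idx))
        spec = spectrum_from_lengths(lengths, n_pairs, genome, bin_edges)
        return fit_ne(spec, grid=grid, smooth_penalty=smooth_penalty, tail=tail)

    point = fit_over(list(range(len(chunks))))
    reps = np.empty((n_boot, len(point.ne)))
    for b in range(n_boot):
        idx = rng.integers(0, len(chunks), size=len(chunks)).tolist()
        reps[b] = fit_over(idx).ne
    lwr = np.minimum(np.percentile(reps, 2.5, axis=0), point.ne)
    upr = np.maximum(np.percentile(reps, 97.5, axis=0), point.ne)
    return NeTrajectory(generations=point.generations, ne=point.ne, lwr=lwr, upr=upr)
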