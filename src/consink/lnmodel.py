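"""Linear-nonlinear Poisson nested encoding models.

Spike counts in 100-ms windows are modelled as Poisson with rate
``exp(sum_v w_v[bin_v(t)])`` over variable subsets of {relative direction to
the sink (RD, 18 circular bins), distance to the sink (Ds, 20 linear bins),
allocentric direction to the sink (AD, 18 circular bins)} — seven models.
Parameters maximise the Poisson log likelihood with a quadratic penalty on
the second differences of each tuning vector (circular wrap for RD/AD).
Tenfold cross-validation with interleaved contiguous sections scores each
model by its test log-likelihood increase over the mean-rate model, in
bits/spike; the selected model is the simplest one that significantly beats
the mean-rate model and every nested simpler model (one-sided Wilcoxon
signed-rank across folds).
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._circ import wrap_180, wrap_360
from .prep import PosedSpikes
from .synth import Tracking

__all__ = [
    "DesignMatrix",
    "LNFit",
    "LNResult",
    "MODELS",
    "build_design",
    "fit_ln",
    "select_model",
    "response_profiles",
    "run_ln_analysis",
]

VARIABLES = ("RD", "Ds", "AD")
MODELS = tuple(
    "+".join(c)
    for r in (1, 2, 3)
    for c in itertools.combinations(VARIABLES, r)
)
DEFAULT_BINS = {"RD": 18, "Ds": 20, "AD": 18}
CIRCULAR = {"RD": True, "Ds": False, "AD": True}


@dataclass
class DesignMatrix:
    """Window-level spike counts and binned state variables.

    The one-hot blocks of the underlying design are stored implicitly as
    integer bin indices per window (each block trivially sums to one per
    window)."""

    counts: np.ndarray  # (n,) spikes per window
    idx: dict  # variable -> (n,) bin index
    n_bins: dict  # variable -> number of bins
    window: float  # s
    ds_max: float  # cm; Ds bin edges span [0, ds_max]
    t_centers: np.ndarray = field(default=None)

    @property
    def n_windows(self) -> int:
        return len(self.counts)


def build_design(
    spikes: PosedSpikes,
    tracking: Tracking,
    sink,
    window: float = 0.1,
    exclusion_windows=None,
    n_bins: dict | None = None,
) -> DesignMatrix:
    """Bin the session into 100-ms windows and compute RD/AD/Ds from the
    occupancy-weighted mean pose within each window.

    Windows with no tracking frames, and windows overlapping an exclusion
    interval, are dropped whole (their spikes are not counted).
    """
    n_bins = dict(DEFAULT_BINS, **(n_bins or {}))
    sink = np.asarray(sink, float)
    t0, t1 = tracking.t[0], tracking.t[-1]
    n_win = int(np.floor((t1 - t0) / window))
    if n_win < 10:
        raise ValueError("session shorter than 10 windows")
    edges = t0 + window * np.arange(n_win + 1)

    wi = np.clip(((tracking.t - t0) / window).astype(int), 0, n_win - 1)
    in_span = tracking.t < edges[-1]
    wi = wi[in_span]
    nf = np.bincount(wi, minlength=n_win).astype(float)
    mx = np.bincount(wi, weights=tracking.head_xy[in_span, 0], minlength=n_win)
    my = np.bincount(wi, weights=tracking.head_xy[in_span, 1], minlength=n_win)
    ang = np.deg2rad(tracking.head_dir[in_span])
    mc = np.bincount(wi, weights=np.cos(ang), minlength=n_win)
    ms = np.bincount(wi, weights=np.sin(ang), minlength=n_win)

    keep = nf > 0
    if exclusion_windows:
        for a, b in exclusion_windows:
            keep &= ~((edges[:-1] < b) & (edges[1:] > a))
    mx, my = mx[keep] / nf[keep], my[keep] / nf[keep]
    hd = np.rad2deg(np.arctan2(ms[keep], mc[keep])) % 360.0

    st = spikes.t[(spikes.t >= t0) & (spikes.t < edges[-1])]
    swi = np.clip(((st - t0) / window).astype(int), 0, n_win - 1)
    counts = np.bincount(swi, minlength=n_win)[keep].astype(float)

    dx, dy = sink[0] - mx, sink[1] - my
    brg = np.rad2deg(np.arctan2(dy, dx))
    rd = wrap_180(hd - brg)
    ad = wrap_360(brg)
    ds = np.hypot(dx, dy)
    ds_max = float(ds.max())

    idx = {
        "RD": np.clip(((rd + 180.0) / (360.0 / n_bins["RD"])).astype(int), 0, n_bins["RD"] - 1),
        "AD": np.clip((ad / (360.0 / n_bins["AD"])).astype(int), 0, n_bins["AD"] - 1),
        "Ds": np.clip((ds / (ds_max / n_bins["Ds"] + 1e-300)).astype(int), 0, n_bins["Ds"] - 1),
    }
    tc = (edges[:-1] + window / 2)[keep]
    return DesignMatrix(counts, idx, n_bins, window, ds_max, tc)


# ---------------------------------------------------------------------------
# penalized Poisson fitting
# ---------------------------------------------------------------------------
def _penalty_matrix(n: int, circular: bool, beta: float) -> np.ndarray:
    """beta * D'D for the second-difference operator D (circular wrap for
    direction variables)."""
    if circular:
        D = np.zeros((n, n))
        for i in range(n):
            D[i, (i - 1) % n] = 1.0
            D[i, i] = -2.0
            D[i, (i + 1) % n] = 1.0
    else:
        D = np.zeros((max(n - 2, 0), n))
        for i in range(n - 2):
            D[i, i : i + 3] = (1.0, -2.0, 1.0)
    return beta * (D.T @ D)


def _fit_newton(idx_list, nb_list, counts, P, w0=None, tol=1e-6, max_iter=100):
    """Damped Newton on the convex penalized Poisson objective.

    Returns (weights, converged).  The Hessian is assembled exactly from
    per-bin and cross-bin accumulations of the window rates.
    """
    sizes = list(nb_list)
    starts = np.concatenate([[0], np.cumsum(sizes)]).astype(int)
    dim = starts[-1]
    w = np.zeros(dim) if w0 is None else w0.copy()
    mean_c = max(counts.mean(), 1e-10)
    if w0 is None:
        w[:] = np.log(mean_c) / len(sizes)

    def rate(wv):
        eta = np.zeros(len(counts))
        for b, idx in enumerate(idx_list):
            eta += wv[starts[b] + idx]
        return np.exp(np.clip(eta, -30, 30))

    def objective(wv):
        lam = rate(wv)
        return float(np.sum(lam - counts * np.log(np.maximum(lam, 1e-300)))
                     + wv @ P @ wv)

    f = objective(w)
    converged = False
    for _ in range(max_iter):
        lam = rate(w)
        g = 2.0 * P @ w
        H = 2.0 * P.copy()
        for b, idx in enumerate(idx_list):
            sl = slice(starts[b], starts[b + 1])
            g[sl] += np.bincount(idx, weights=lam - counts, minlength=sizes[b])
            d = np.bincount(idx, weights=lam, minlength=sizes[b])
            H[sl, sl] += np.diag(d)
            for b2 in range(b + 1, len(idx_list)):
                sl2 = slice(starts[b2], starts[b2 + 1])
                cross = np.bincount(
                    idx * sizes[b2] + idx_list[b2], weights=lam,
                    minlength=sizes[b] * sizes[b2],
                ).reshape(sizes[b], sizes[b2])
                H[sl, sl2] += cross
                H[sl2, sl] += cross.T
        if np.max(np.abs(g)) < tol * (1.0 + abs(f)):
            converged = True
            break
        H[np.diag_indices(dim)] += 1e-8 + 1e-10 * np.trace(H) / dim
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = g / np.maximum(np.diag(H), 1e-8)
        alpha = 1.0
        for _ls in range(30):
            w_new = w - alpha * step
            f_new = objective(w_new)
            if f_new <= f + 1e-12:
                break
            alpha *= 0.5
        else:
            converged = np.max(np.abs(g)) < 1e-3 * (1.0 + abs(f))
            break
        if abs(f - f_new) < 1e-12 * (1.0 + abs(f)):
            w, f = w_new, f_new
            converged = True
            break
        w, f = w_new, f_new
    return w, converged


def _poisson_llh(counts, lam):
    """Poisson log likelihood up to the count-factorial constant (which
    cancels in every comparison), in nats."""
    return float(np.sum(counts * np.log(np.maximum(lam, 1e-300)) - lam))


def _fold_assignment(n: int, folds: int = 10, sections_per_fold: int = 5) -> np.ndarray:
    """Interleaved contiguous sections: the data are cut into
    folds*sections_per_fold contiguous sections and section s goes to fold
    ``s % folds``."""
    n_sections = folds * sections_per_fold
    sec = np.minimum((np.arange(n) * n_sections) // max(n, 1), n_sections - 1)
    return (sec % folds).astype(int)


@dataclass
class LNFit:
    model: str
    fold_gains: np.ndarray  # (folds,) bits/spike vs the mean-rate model
    weights: dict  # variable -> full-data tuning vector
    converged: np.ndarray  # (folds,) bool

    @property
    def mean_gain(self) -> float:
        return float(np.mean(self.fold_gains))


def fit_ln(
    design: DesignMatrix,
    variables,
    beta: float = 1.0,
    folds: int = 10,
) -> LNFit:
    """Fit one variable-subset model with tenfold cross-validation.

    Returns per-fold test log-likelihood gains over the mean-rate model in
    bits/spike, plus the tuning vectors re-fitted on the full data.
    """
    variables = [v for v in VARIABLES if v in variables]
    if not variables:
        raise ValueError("need at least one variable")
    counts = design.counts
    idx_all = [design.idx[v] for v in variables]
    nb = [design.n_bins[v] for v in variables]
    P = np.zeros((sum(nb), sum(nb)))
    pos = 0
    for v, n in zip(variables, nb):
        P[pos : pos + n, pos : pos + n] = _penalty_matrix(n, CIRCULAR[v], beta)
        pos += n
    fold_of = _fold_assignment(design.n_windows, folds)
    gains = np.zeros(folds)
    ok = np.zeros(folds, dtype=bool)
    starts = np.concatenate([[0], np.cumsum(nb)]).astype(int)
    w_warm = None
    for f in range(folds):
        train = fold_of != f
        test = ~train
        idx_tr = [ix[train] for ix in idx_all]
        w, conv = _fit_newton(idx_tr, nb, counts[train], P, w0=w_warm)
        w_warm = w
        ok[f] = conv
        eta = np.zeros(int(test.sum()))
        for b, v in enumerate(variables):
            eta += w[starts[b] + design.idx[v][test]]
        lam = np.exp(np.clip(eta, -30, 30))
        lam0 = max(counts[train].mean(), 1e-10)
        n_test_spikes = counts[test].sum()
        if n_test_spikes > 0:
            gains[f] = (
                _poisson_llh(counts[test], lam)
                - _poisson_llh(counts[test], np.full(int(test.sum()), lam0))
            ) / (np.log(2.0) * n_test_spikes)
    w_full, _ = _fit_newton(idx_all, nb, counts, P, w0=w_warm)
    weights = {
        v: w_full[starts[b] : starts[b + 1]] for b, v in enumerate(variables)
    }
    return LNFit("+".join(variables), gains, weights, ok)


def response_profiles(fit: LNFit) -> dict:
    """Per-variable response profiles: exp(weights), normalised to mean 1."""
    out = {}
    for v, w in fit.weights.items():
        prof = np.exp(w - w.max())
        out[v] = prof / prof.mean()
    return out


@dataclass
class LNResult:
    fits: dict  # model label -> LNFit
    selected: str | None

    def to_dict(self) -> dict:
        return {
            "selected": self.selected,
            "models": {
                m: {
                    "fold_gains": list(map(float, f.fold_gains)),
                    "mean_gain": f.mean_gain,
                }
                for m, f in self.fits.items()
            },
        }


def _signed_rank_greater(x, y=None, alpha=0.05) -> bool:
    """One-sided Wilcoxon signed-rank: is the (paired) median of x (or x-y)
    significantly greater than zero?"""
    d = np.asarray(x, float) if y is None else np.asarray(x, float) - np.asarray(y, float)
    if np.allclose(d, 0):
        return False
    try:
        p = stats.wilcoxon(d, alternative="greater", zero_method="wilcox").pvalue
    except ValueError:
        return False
    return bool(p < alpha)


def select_model(fits: dict, alpha: float = 0.05) -> str | None:
    """Forward selection across the seven models.

    The best model of each size (by mean cross-validated gain) is found;
    starting from the best single-variable model, the selection steps up to
    the larger model only while the increase in fold gains is significant
    (one-sided signed rank), so the result is the simplest model that beats
    every simpler stage.  The final model must itself significantly beat the
    mean-rate model; otherwise None is returned.
    """
    by_size = {}
    for m in MODELS:
        if m not in fits:
            continue
        size = len(m.split("+"))
        if size not in by_size or fits[m].mean_gain > fits[by_size[size]].mean_gain:
            by_size[size] = m
    if not by_size:
        return None
    current = by_size[min(by_size)]
    for size in sorted(by_size):
        if size <= len(current.split("+")):
            continue
        challenger = by_size[size]
        if _signed_rank_greater(
            fits[challenger].fold_gains, fits[current].fold_gains, alpha=alpha
        ):
            current = challenger
        else:
            break
    if not _signed_rank_greater(fits[current].fold_gains, alpha=alpha):
        return None
    return current


def run_ln_analysis(
    spikes: PosedSpikes,
    tracking: Tracking,
    sink,
    beta: float = 1.0,
    folds: int = 10,
    window: float = 0.1,
    exclusion_windows=None,
) -> LNResult:
    """Fit all seven models for one cell and select the best description."""
    design = build_design(spikes, tracking, sink, window, exclusion_windows)
    fits = {}
    for m in MODELS:
        fits[m] = fit_ln(design, m.split("+"), beta=beta, folds=folds)
    return LNResult(fits, select_model(fits))
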