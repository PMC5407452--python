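"""Four-parameter sigmoid ("BALT") model of developmental expression transitions.

The model describes the log2 expression of a gene across developmental time
``t`` (days post conception, dpc) as a logistic transition between two plateaus:

    X(t) = B + A / (1 + exp(f(T) * (L - t)))

with

* ``B`` ("basis") — the starting expression level (log2),
* ``A`` ("amplitude") — the signed log2 change between the finishing and the
  starting level; negative for down-regulated genes,
* ``L`` ("localisation") — the inflexion time in dpc, i.e. when the gene is
  half way through its transition,
* ``T`` ("transition") — the duration of the transition in days.

The rate sub-function is calibrated as ``f(T) = 2 ln 9 / T`` so that ``T`` is
exactly the time the curve takes to move from 10% to 90% of its amplitude.
Other calibrations can be plugged in through :func:`transition_rate`.

The module provides evaluation, bounded multi-start least-squares fitting,
nested model selection against a constant model (BIC), random-walk Metropolis
sampling for parameter uncertainty, profile classification, onset-window
summaries over gene sets, and matching of genes against a reference profile.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "BALTParams",
    "BALTFit",
    "FitOptions",
    "MCMCOptions",
    "MCMCSummary",
    "OnsetSummary",
    "transition_rate",
    "balt_evaluate",
    "balt_fit",
    "constant_fit",
    "select_model",
    "balt_mcmc",
    "classify_profile",
    "onset_window",
    "match_reference",
]

#: Default minimum |A| (log2) below which a fitted sigmoid is called flat.
#: 0.58 log2 units is approximately a 1.5-fold change.
MIN_AMPLITUDE = 0.58

#: Exponent saturation limit; beyond this the logistic is evaluated at its
#: asymptote to avoid overflow.
_EXP_CLIP = 700.0


@dataclass(frozen=True)
class BALTParams:
    """Parameters of the sigmoid transition model."""

    B: float
    A: float
    L: float
    T: float

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"transition duration T must be positive, got {self.T}")
        if not math.isfinite(self.L):
            raise ValueError("localisation L must be finite")


@dataclass
class BALTFit:
    """Result of fitting the constant or sigmoid model to one time course.

    ``covariance`` is the 4x4 Gauss-Newton parameter covariance (order
    B, A, L, T) and is only present for converged sigmoid fits.
    """

    params: BALTParams | None
    model: str  # "constant" or "sigmoid"
    rss: float
    r2: float
    n: int
    converged: bool
    B: float = 0.0
    covariance: np.ndarray | None = None
    bic: float | None = None
    delta_bic: float | None = None  # BIC(constant) - BIC(sigmoid); >0 favours sigmoid

    def evaluate(self, t):
        if self.model == "constant":
            return np.broadcast_to(self.B, np.shape(t)).astype(float).copy() \
                if np.ndim(t) else float(self.B)
        return balt_evaluate(self.params, t)


@dataclass(frozen=True)
class FitOptions:
    """Options for :func:`balt_fit`.

    ``l_quantiles`` are the quantiles of the observed times used as
    multi-start initial values for L. Bounds follow the data: L within the
    observed span padded by half a span on each side, T between ``t_min``
    days and three spans, B and A within the data range padded by
    ``range_pad`` log2 units.
    """

    l_quantiles: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9)
    t_min: float = 0.1
    range_pad: float = 2.0
    ftol: float = 1e-12
    xtol: float = 1e-12
    gtol: float = 1e-12


@dataclass(frozen=True)
class MCMCOptions:
    chains: int = 4
    iterations: int = 5000
    burn_in: int = 1000
    seed: int = 0
    #: optional explicit prior box as {"B": (lo, hi), ...} overriding the
    #: fit-derived bounds; collapsing a bound to a point pins the parameter.
    prior_bounds: Mapping[str, tuple[float, float]] | None = None


@dataclass
class MCMCSummary:
    """Posterior summaries (median and central 95% interval) per parameter."""

    median: dict[str, float]
    lower: dict[str, float]
    upper: dict[str, float]
    acceptance_rate: float
    chains: int
    iterations: int
    burn_in: int
    seed: int


@dataclass
class OnsetSummary:
    """Distribution of fitted onset times over a set of switch-like genes."""

    n_genes: int
    mean_l: float
    median_l: float
    iqr_l: tuple[float, float]
    mean_t: float


def transition_rate(T: float) -> float:
    """Rate constant ``f(T) = 2 ln 9 / T``.

    This calibration makes ``T`` the exact 10% -> 90% rise (or fall) time of
    the logistic in days.
    """
    if not T > 0:
        raise ValueError(f"transition duration T must be positive, got {T}")
    return 2.0 * math.log(9.0) / T


def balt_evaluate(params: BALTParams, t):
    """Evaluate the sigmoid model at time(s) ``t`` (dpc).

    Numerically stable for arbitrarily large |exponent|: the logistic
    saturates to its asymptotes B and B + A.
    """
    e = np.clip(transition_rate(params.T) * (params.L - np.asarray(t, dtype=float)),
                -_EXP_CLIP, _EXP_CLIP)
    out = params.B + params.A / (1.0 + np.exp(e))
    return float(out) if np.ndim(t) == 0 else out


def _sigmoid_raw(theta: np.ndarray, t: np.ndarray) -> np.ndarray:
    b, a, loc, dur = theta
    e = np.clip(2.0 * math.log(9.0) / dur * (loc - t), -_EXP_CLIP, _EXP_CLIP)
    return b + a / (1.0 + np.exp(e))


def _check_time_course(times, values, min_points: int) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.ndim != 1 or y.shape != t.shape:
        raise ValueError("times and values must be 1-D and of equal length")
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
        raise ValueError("times and values must be finite")
    if np.unique(t).size < min_points:
        raise ValueError(
            f"need at least {min_points} distinct time points, got {np.unique(t).size}"
        )
    return t, y


def constant_fit(times, values) -> BALTFit:
    """Fit the constant (flat) model: a single level B."""
    t, y = _check_time_course(times, values, 1)
    b = float(np.mean(y))
    rss = float(np.sum((y - b) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    return BALTFit(params=None, model="constant", rss=rss, r2=r2,
                   n=t.size, converged=True, B=b)


def _fit_bounds(t: np.ndarray, y: np.ndarray, opts: FitOptions):
    span = float(t.max() - t.min())
    span = max(span, 1.0)
    yrange = float(y.max() - y.min())
    lo = np.array([y.min() - opts.range_pad,
                   -(yrange + 2 * opts.range_pad),
                   t.min() - span / 2.0,
                   opts.t_min])
    hi = np.array([y.max() + opts.range_pad,
                   yrange + 2 * opts.range_pad,
                   t.max() + span / 2.0,
                   3.0 * span])
    return lo, hi, span


def balt_fit(times, values, opts: FitOptions | None = None) -> BALTFit:
    """Least-squares fit of the sigmoid model with multi-start initialisation.

    Minimises the residual sum of squares with a bounded trust-region
    gradient-following algorithm, started from a small grid of candidate
    inflexion times (quantiles of the observed times). Among converged starts
    the best RSS wins; near-ties are broken towards smaller |A| and then
    earlier L (parsimony). The parameter covariance is the Gauss-Newton
    estimate ``s^2 (J'J)^-1`` from the Jacobian at the optimum.
    """
    opts = opts or FitOptions()
    t, y = _check_time_course(times, values, 5)
    lo, hi, span = _fit_bounds(t, y, opts)

    # Data-driven starting values: B from the earliest tertile, A from the
    # difference to the latest tertile, T a quarter of the span.
    order = np.argsort(t, kind="stable")
    third = max(1, t.size // 3)
    b0 = float(np.mean(y[order[:third]]))
    a0 = float(np.mean(y[order[-third:]]) - b0)
    t0 = span / 4.0
    l_starts = np.quantile(t, opts.l_quantiles)

    def resid(theta):
        return _sigmoid_raw(theta, t) - y

    best = None  # (rss, |A|, L, result)
    for l0 in l_starts:
        x0 = np.clip(np.array([b0, a0, l0, t0]), lo + 1e-9, hi - 1e-9)
        try:
            res = optimize.least_squares(
                resid, x0, bounds=(lo, hi), method="trf",
                ftol=opts.ftol, xtol=opts.xtol, gtol=opts.gtol,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if not np.all(np.isfinite(res.x)):
            continue
        rss = float(2.0 * res.cost)
        key = (rss, abs(res.x[1]), res.x[2])
        if best is None or _better_fit(key, best[0]):
            best = (key, res)

    if best is None:
        raise RuntimeError("sigmoid fit failed from every start")
    _, res = best
    rss = float(2.0 * res.cost)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    params = BALTParams(*[float(v) for v in res.x])

    dof = t.size - 4
    cov = None
    if dof > 0:
        jtj = res.jac.T @ res.jac
        with np.errstate(all="ignore"):
            cov = np.linalg.pinv(jtj) * (rss / dof)
    return BALTFit(params=params, model="sigmoid", rss=rss, r2=r2, n=t.size,
                   converged=bool(res.success), B=params.B, covariance=cov)


def _better_fit(key, ref, rel_tol: float = 1e-9) -> bool:
    """Compare (rss, |A|, L) tuples; RSS decides except for near-ties."""
    rss, abs_a, loc = key
    rss_r, abs_a_r, loc_r = ref
    scale = max(rss, rss_r, 1e-12)
    if abs(rss - rss_r) > rel_tol * scale:
        return rss < rss_r
    if abs_a != abs_a_r:
        return abs_a < abs_a_r
    return loc < loc_r


def _gaussian_bic(rss: float, n: int, k_params: int) -> float:
    """BIC under i.i.d. Gaussian errors; k_params counts mean-model
    parameters, the noise variance adds one more."""
    rss = max(rss, 1e-300)
    return n * math.log(rss / n) + (k_params + 1) * math.log(n)


def select_model(times, values, opts: FitOptions | None = None) -> BALTFit:
    """Fit the constant and the full sigmoid model; keep the BIC winner.

    ``delta_bic = BIC(constant) - BIC(sigmoid)`` is stored on the returned
    fit; positive values favour the sigmoid.
    """
    flat = constant_fit(times, values)
    sig = balt_fit(times, values, opts)
    n = flat.n
    bic_flat = _gaussian_bic(flat.rss, n, 1)
    bic_sig = _gaussian_bic(sig.rss, n, 4)
    delta = bic_flat - bic_sig
    winner = sig if (delta > 0 and sig.converged) else flat
    winner.bic = bic_sig if winner is sig else bic_flat
    winner.delta_bic = delta
    return winner


_PARAM_NAMES = ("B", "A", "L", "T", "sigma2")


def balt_mcmc(fit: BALTFit, times, values,
              opts: MCMCOptions | None = None) -> MCMCSummary:
    """Random-walk Metropolis sampling of the sigmoid parameters.

    The chain walks in (B, A, L, log T, log sigma^2) with Gaussian proposals
    whose covariance is the Gauss-Newton covariance of the least-squares fit
    scaled by 2.4^2/5 (the classic multivariate random-walk tuning), a flat
    prior over the fit's parameter box, and a Gaussian likelihood. Summaries
    are pooled over chains after burn-in and reported on the natural scale.
    """
    opts = opts or MCMCOptions()
    if fit.model != "sigmoid" or not fit.converged or fit.params is None:
        raise ValueError("MCMC requires a converged sigmoid fit")
    t, y = _check_time_course(times, values, 5)
    n = t.size

    p = fit.params
    sigma2_hat = max(fit.rss / max(n - 4, 1), 1e-12)
    theta0 = np.array([p.B, p.A, p.L, math.log(p.T), math.log(sigma2_hat)])

    # Prior box (flat): fit bounds on (B, A, L, T), broad box on sigma2.
    lo4, hi4, _ = _fit_bounds(t, y, FitOptions())
    lo = np.array([lo4[0], lo4[1], lo4[2], math.log(lo4[3]), math.log(sigma2_hat) - 10])
    hi = np.array([hi4[0], hi4[1], hi4[2], math.log(hi4[3]), math.log(sigma2_hat) + 10])
    if opts.prior_bounds:
        for i, name in enumerate(_PARAM_NAMES):
            if name in opts.prior_bounds:
                a, b = opts.prior_bounds[name]
                if name == "T":
                    a, b = math.log(a), math.log(b)
                elif name == "sigma2":
                    a, b = math.log(a), math.log(b)
                lo[i], hi[i] = a, b
    theta0 = np.clip(theta0, lo, hi)

    # Proposal covariance from the LM covariance (delta method for log T),
    # with a weak fallback on the diagonal.
    prop_cov = np.zeros((5, 5))
    if fit.covariance is not None and np.all(np.isfinite(fit.covariance)):
        c4 = np.array(fit.covariance, dtype=float)
        jac = np.diag([1.0, 1.0, 1.0, 1.0 / p.T])
        prop_cov[:4, :4] = jac @ c4 @ jac.T
    diag = np.diag(prop_cov).copy()
    fallback = np.array([0.1, 0.1, 1.0, 0.1, 0.0]) ** 2
    for i in range(4):
        if not np.isfinite(diag[i]) or diag[i] <= 0:
            prop_cov[i, i] = fallback[i]
    prop_cov[4, 4] = 2.0 / n  # asymptotic var of log sigma^2
    prop_cov *= 2.4 ** 2 / 5.0
    try:
        chol = np.linalg.cholesky(prop_cov + 1e-12 * np.eye(5))
    except np.linalg.LinAlgError:
        chol = np.diag(np.sqrt(np.abs(np.diag(prop_cov)) + 1e-12))

    def log_post(theta):
        if np.any(theta < lo) or np.any(theta > hi):
            return -np.inf
        sig2 = math.exp(theta[4])
        mu = _sigmoid_raw([theta[0], theta[1], theta[2], math.exp(theta[3])], t)
        rss = float(np.sum((y - mu) ** 2))
        return -0.5 * (n * math.log(sig2) + rss / sig2)

    rng = np.random.default_rng(opts.seed)
    keep = []
    n_accept = 0
    n_prop = 0
    for _chain in range(opts.chains):
        theta = theta0.copy()
        lp = log_post(theta)
        draws = np.empty((opts.iterations, 5))
        for it in range(opts.iterations):
            step = chol @ rng.standard_normal(5)
            cand = theta + step
            lp_c = log_post(cand)
            n_prop += 1
            if lp_c - lp > math.log(rng.random() + 1e-300):
                theta, lp = cand, lp_c
                n_accept += 1
            draws[it] = theta
        keep.append(draws[opts.burn_in:])
    samples = np.vstack(keep)
    # back to natural scale
    nat = samples.copy()
    nat[:, 3] = np.exp(samples[:, 3])
    nat[:, 4] = np.exp(samples[:, 4])

    q = np.quantile(nat, [0.025, 0.5, 0.975], axis=0)
    return MCMCSummary(
        median={k: float(q[1, i]) for i, k in enumerate(_PARAM_NAMES)},
        lower={k: float(q[0, i]) for i, k in enumerate(_PARAM_NAMES)},
        upper={k: float(q[2, i]) for i, k in enumerate(_PARAM_NAMES)},
        acceptance_rate=n_accept / max(n_prop, 1),
        chains=opts.chains, iterations=opts.iterations,
        burn_in=opts.burn_in, seed=opts.seed,
    )


def classify_profile(fit: BALTFit, window: tuple[float, float],
                     min_amplitude: float = MIN_AMPLITUDE) -> str:
    """Classify a fitted profile within an observation window.

    Returns one of ``flat``, ``switch_up``, ``switch_down`` or
    ``curvilinear_incomplete``. A sigmoid whose transition (L +/- T/2)
    completes inside the window is a switch; one still in progress at the
    window edge — the SOX9-like case — is curvilinear/incomplete. Amplitudes
    below ``min_amplitude`` (default ~1.5-fold) are called flat.
    """
    t_min, t_max = window
    if not t_min < t_max:
        raise ValueError(f"invalid window {window}")
    if fit.model == "constant" or fit.params is None:
        return "flat"
    p = fit.params
    if abs(p.A) < min_amplitude:
        return "flat"
    if (p.L - p.T / 2.0 >= t_min and p.L + p.T / 2.0 <= t_max
            and p.T <= (t_max - t_min)):
        return "switch_up" if p.A > 0 else "switch_down"
    return "curvilinear_incomplete"


def onset_window(fits: Iterable[BALTFit],
                 window: tuple[float, float] | None = None,
                 min_amplitude: float = MIN_AMPLITUDE) -> OnsetSummary:
    """Summarise fitted onset times L over switch-classified fits.

    Flat and curvilinear fits are excluded. If ``window`` is None, fits are
    taken at face value (any non-flat sigmoid counts as a switch).
    """
    ls, ts = [], []
    for fit in fits:
        if fit.model != "sigmoid" or fit.params is None:
            continue
        if window is not None:
            if not classify_profile(fit, window, min_amplitude).startswith("switch"):
                continue
        elif abs(fit.params.A) < min_amplitude:
            continue
        ls.append(fit.params.L)
        ts.append(fit.params.T)
    if not ls:
        raise ValueError("no switch-classified fits to summarise")
    ls_arr = np.asarray(ls)
    q1, med, q3 = np.percentile(ls_arr, [25, 50, 75])
    return OnsetSummary(n_genes=len(ls), mean_l=float(ls_arr.mean()),
                        median_l=float(med), iqr_l=(float(q1), float(q3)),
                        mean_t=float(np.mean(ts)))


def match_reference(fits: Mapping[str, BALTFit], reference_gene: str,
                    tol_l: float, tol_t: float,
                    window: tuple[float, float],
                    min_amplitude: float = MIN_AMPLITUDE) -> list[str]:
    """Genes whose fitted dynamics resemble a reference gene's.

    A match shares the reference's classification label and amplitude sign,
    has |A| >= ``min_amplitude``, and fitted (L, T) within ``tol_l`` /
    ``tol_t`` days of the reference. For curvilinear (incomplete) references
    T is weakly identified, so only L is compared, with tolerance 2*tol_l.
    The reference matches itself. Returned sorted by |L - L_ref|.
    """
    if reference_gene not in fits:
        raise KeyError(f"reference gene {reference_gene!r} has no fit")
    ref = fits[reference_gene]
    ref_label = classify_profile(ref, window, min_amplitude)
    if ref_label == "flat":
        raise ValueError(f"reference gene {reference_gene!r} fits a flat profile")
    rp = ref.params
    curvi = ref_label == "curvilinear_incomplete"
    out = []
    for gene, fit in fits.items():
        if fit.model != "sigmoid" or fit.params is None:
            continue
        p = fit.params
        if classify_profile(fit, window, min_amplitude) != ref_label:
            continue
        if np.sign(p.A) != np.sign(rp.A) or abs(p.A) < min_amplitude:
            continue
        if curvi:
            if abs(p.L - rp.L) > 2.0 * tol_l:
                continue
        else:
            if abs(p.L - rp.L) > tol_l or abs(p.T - rp.T) > tol_t:
                continue
        out.append((abs(p.L - rp.L), gene))
    return [g for _, g in sorted(out)]
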