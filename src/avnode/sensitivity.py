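"""Distribution-based global sensitivity analysis of RR-series
characteristics with respect to the model and AA-series parameters.

For each parameter column the observed range is split into ``C``
equal-width conditioning intervals; the sensitivity coefficient is the
median over intervals of the median Kolmogorov-Smirnov distance between
each interval's conditional empirical CDF and ``D`` bootstrap replicates
of the unconditional CDF (each of size ``K // C``).  A dummy threshold --
the median KS distance between bootstrap replicates of the unconditional
CDF itself -- provides the significance floor: a parameter is influential
iff its coefficient exceeds it.

Parameter sets are screened before any CDF is built: the slow pathway
must have a strictly lower refractory period and strictly higher
conduction delay than the fast pathway at every excitation gap (checked
on a dense gap grid plus the asymptote), and the simulated mean RR
interval must lie in [300, 1000] ms.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atrial_generator import AAParams, sample_intervals
from .av_network import DEFAULT_CN_PARAMS, ModelParams, PathwayParams, simulate
from .rr_metrics import (
    MetricConfig,
    RRSeries,
    SampleEntropyUndefined,
    rr_mean,
    rr_rmssd,
    rr_sample_entropy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PARAM_NAMES",
    "OUTPUT_NAMES",
    "ParameterSpace",
    "SensitivityResult",
    "sample_parameter_sets",
    "physiological_filter",
    "pathway_ordering_ok",
    "ks_distance",
    "sensitivity_coefficient",
    "dummy_threshold",
    "run_sensitivity_study",
]

#: Column order of the 14-dimensional parameter vector.
PARAM_NAMES = [
    "r_min_sp", "delta_r_sp", "tau_r_sp", "d_min_sp", "delta_d_sp", "tau_d_sp",
    "r_min_fp", "delta_r_fp", "tau_r_fp", "d_min_fp", "delta_d_fp", "tau_d_fp",
    "mu", "sigma",
]

OUTPUT_NAMES = ["rr_mean", "rr_rmssd", "rr_sampen"]

#: Uniform sampling bounds of the study box (ms).
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "r_min_sp": (250.0, 600.0), "delta_r_sp": (0.0, 600.0),
    "tau_r_sp": (50.0, 300.0), "d_min_sp": (0.0, 30.0),
    "delta_d_sp": (0.0, 75.0), "tau_d_sp": (50.0, 300.0),
    "r_min_fp": (250.0, 600.0), "delta_r_fp": (0.0, 600.0),
    "tau_r_fp": (50.0, 300.0), "d_min_fp": (0.0, 30.0),
    "delta_d_fp": (0.0, 75.0), "tau_d_fp": (50.0, 300.0),
    "mu": (100.0, 250.0), "sigma": (15.0, 30.0),
}


@dataclass(frozen=True)
class ParameterSpace:
    """Per-parameter uniform bounds; the coupling-node parameters are fixed."""

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    cn: PathwayParams = DEFAULT_CN_PARAMS

    def __post_init__(self) -> None:
        if set(self.bounds) != set(PARAM_NAMES):
            missing = set(PARAM_NAMES) - set(self.bounds)
            extra = set(self.bounds) - set(PARAM_NAMES)
            raise ValueError(f"bad bounds keys: missing={missing}, extra={extra}")
        for name, (lo, hi) in self.bounds.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with low < high")

    def as_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in PARAM_NAMES])
        hi = np.array([self.bounds[n][1] for n in PARAM_NAMES])
        return lo, hi


def sample_parameter_sets(
    space: ParameterSpace, K: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Draw ``K`` parameter rows, each column uniform within its bounds."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lo, hi = space.as_arrays()
    return lo + (hi - lo) * rng.random((K, len(PARAM_NAMES)))


def row_to_model_params(row: np.ndarray, cn: PathwayParams = DEFAULT_CN_PARAMS
                        ) -> ModelParams:
    """Interpret one parameter row (first 12 entries) as ModelParams."""
    sp = PathwayParams(*row[0:6])
    fp = PathwayParams(*row[6:12])
    return ModelParams(sp=sp, fp=fp, cn=cn)


def _gap_grid(sp: PathwayParams, fp: PathwayParams) -> np.ndarray:
    tau_max = max(sp.tau_r, sp.tau_d, fp.tau_r, fp.tau_d)
    return np.arange(0.0, 10.0 * tau_max + 1.0, 1.0)


def physiological_filter(
    mp: ModelParams, rr_mean_ms: float | None = None
) -> tuple[bool, str]:
    """Accept/reject a parameter set with a reason.

    Criterion (i): R_SP(g) < R_FP(g) and D_SP(g) > D_FP(g) for every gap
    ``g`` on a dense grid [0, 10*max(tau)] at 1 ms steps plus the
    asymptote (exponential curves with different tau may cross between
    endpoints, so endpoint checks are insufficient).
    Criterion (ii): 300 <= mean RR <= 1000 ms (60-200 bpm); skipped when
    ``rr_mean_ms`` is None.
    """
    sp, fp = mp.sp, mp.fp
    g = _gap_grid(sp, fp)
    r_sp = sp.r_min + sp.delta_r * (1.0 - np.exp(-g / sp.tau_r))
    r_fp = fp.r_min + fp.delta_r * (1.0 - np.exp(-g / fp.tau_r))
    if not (np.all(r_sp < r_fp)
            and sp.r_min + sp.delta_r < fp.r_min + fp.delta_r):
        return False, "refractory ordering violated (R_SP must be < R_FP at all gaps)"
    d_sp = sp.d_min + sp.delta_d * np.exp(-g / sp.tau_d)
    d_fp = fp.d_min + fp.delta_d * np.exp(-g / fp.tau_d)
    if not (np.all(d_sp > d_fp) and sp.d_min > fp.d_min):
        return False, "delay ordering violated (D_SP must be > D_FP at all gaps)"
    if rr_mean_ms is not None and not (300.0 <= rr_mean_ms <= 1000.0):
        return False, f"mean RR {rr_mean_ms:.1f} ms outside [300, 1000]"
    return True, "accepted"


def pathway_ordering_ok(X: np.ndarray, n_grid_per_tau: float = 10.0) -> np.ndarray:
    """Vectorized criterion (i) over a (K, >=12) parameter matrix.

    Uses a shared 1 ms gap grid long enough for the largest tau in the
    matrix, plus the analytic asymptotes.
    """
    X = np.asarray(X, dtype=np.float64)
    tau_max = float(np.max(X[:, [2, 5, 8, 11]]))
    g = np.arange(0.0, n_grid_per_tau * tau_max + 1.0, 1.0)
    ok = np.ones(X.shape[0], dtype=bool)
    chunk = max(1, int(5e6 // (g.size + 1)))
    for s in range(0, X.shape[0], chunk):
        e = min(s + chunk, X.shape[0])
        sp = X[s:e, 0:6]
        fp = X[s:e, 6:12]
        r_sp = sp[:, [0]] + sp[:, [1]] * (1.0 - np.exp(-g / sp[:, [2]]))
        r_fp = fp[:, [0]] + fp[:, [1]] * (1.0 - np.exp(-g / fp[:, [2]]))
        c = np.all(r_sp < r_fp, axis=1)
        c &= sp[:, 0] + sp[:, 1] < fp[:, 0] + fp[:, 1]
        d_sp = sp[:, [3]] + sp[:, [4]] * np.exp(-g / sp[:, [5]])
        d_fp = fp[:, [3]] + fp[:, [4]] * np.exp(-g / fp[:, [5]])
        c &= np.all(d_sp > d_fp, axis=1)
        c &= sp[:, 3] > fp[:, 3]
        ok[s:e] = c
    return ok


def ks_distance(sample_a, sample_b) -> float:
    """Maximum absolute difference between two empirical CDFs."""
    a = np.sort(np.asarray(sample_a, dtype=np.float64))
    b = np.sort(np.asarray(sample_b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("samples must be non-empty")
    pooled = np.concatenate([a, b])
    fa = np.searchsorted(a, pooled, side="right") / a.size
    fb = np.searchsorted(b, pooled, side="right") / b.size
    return float(np.max(np.abs(fa - fb)))


def _ks_sorted_vs_batch(cond_sorted: np.ndarray, boot_sorted: np.ndarray
                        ) -> np.ndarray:
    """KS distance of one sorted sample against each row of a sorted batch."""
    out = np.empty(boot_sorted.shape[0])
    nb = boot_sorted.shape[1]
    nc = cond_sorted.size
    for d in range(boot_sorted.shape[0]):
        row = boot_sorted[d]
        pooled = np.concatenate([cond_sorted, row])
        fc = np.searchsorted(cond_sorted, pooled, side="right") / nc
        fb = np.searchsorted(row, pooled, side="right") / nb
        out[d] = np.max(np.abs(fc - fb))
    return out


def _bootstrap_unconditional(
    y: np.ndarray, C: int, D: int, rng: np.random.Generator
) -> np.ndarray:
    size = y.size // C
    if size < 1:
        raise ValueError("fewer samples than conditioning intervals")
    idx = rng.integers(0, y.size, size=(D, size))
    boot = y[idx]
    boot.sort(axis=1)
    return boot


def sensitivity_coefficient(
    x_col,
    y_col,
    C: int = 15,
    D: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float]]:
    """Distribution-based sensitivity coefficient of ``y`` on ``x``.

    Returns ``(S, (lo, hi))`` where S is the median over conditioning
    intervals of the median-over-bootstraps KS distance, and (lo, hi) is
    the 2.5/97.5 percentile interval over bootstrap replicates of the
    median-over-intervals KS distance.
    """
    x = np.asarray(x_col, dtype=np.float64)
    y = np.asarray(y_col, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x_col and y_col must be equal-length vectors")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot = _bootstrap_unconditional(y, C, D, rng)
    edges = np.linspace(x.min(), x.max(), C + 1)
    which = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, C - 1)
    ks_rows = []
    for c in range(C):
        members = np.sort(y[which == c])
        if members.size == 0:
            warnings.warn(f"conditioning interval {c} is empty; skipped")
            continue
        ks_rows.append(_ks_sorted_vs_batch(members, boot))
    if not ks_rows:
        raise ValueError("all conditioning intervals are empty")
    ks_mat = np.vstack(ks_rows)  # (n_nonempty_intervals, D)
    S = float(np.median(np.median(ks_mat, axis=1)))
    per_replicate = np.median(ks_mat, axis=0)
    lo, hi = np.percentile(per_replicate, [2.5, 97.5])
    return S, (float(lo), float(hi))


def dummy_threshold(
    y_col, C: int = 15, D: int = 1000, seed: int | np.random.Generator = 0
) -> float:
    """Noise floor: median KS distance between the first bootstrap
    replicate of the unconditional CDF and each of the remaining ones."""
    y = np.asarray(y_col, dtype=np.float64)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    boot = _bootstrap_unconditional(y, C, D, rng)
    ks = _ks_sorted_vs_batch(boot[0], boot[1:])
    return float(np.median(ks))


@dataclass
class SensitivityResult:
    """Coefficient matrix, dummy thresholds, bootstrap spread and flags."""

    S: pd.DataFrame                 # (14 params x 3 outputs)
    dummy: pd.Series                # per output
    spread_lo: pd.DataFrame
    spread_hi: pd.DataFrame
    influential: pd.DataFrame       # S > dummy
    X: np.ndarray                   # accepted parameter rows
    Y: np.ndarray                   # accepted outputs
    n_generated: int
    n_accepted: int
    reject_counts: dict[str, int]

    @property
    def acceptance_rate(self) -> float:
        return self.n_accepted / self.n_generated

    def ranking(self, output: str) -> list[str]:
        """Parameter names sorted by decreasing coefficient for one output."""
        return list(self.S[output].sort_values(ascending=False).index)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(index=PARAM_NAMES)
        for out in OUTPUT_NAMES:
            short = out.replace("rr_", "")
            df[f"S_{short}"] = self.S[out]
            df[f"dummy_{short}"] = self.dummy[out]
            df[f"influential_{short}"] = self.influential[out].astype(int)
        return df


def run_sensitivity_study(
    space: ParameterSpace | None = None,
    K: int = 5000,
    n_aa: int = 60000,
    n_rr: int = 4000,
    C: int = 15,
    D: int = 1000,
    seed: int = 0,
    min_accepted: int = 10 * 15,
    metric_cfg: MetricConfig = MetricConfig(),
) -> SensitivityResult:
    """Generate, screen and simulate ``K`` parameter sets and compute the
    full 14 x 3 sensitivity-coefficient matrix with dummy thresholds.

    One AA-series seed per parameter row is derived from the master seed
    via a spawned seed sequence, so runs are reproducible regardless of
    evaluation order.
    """
    if space is None:
        space = ParameterSpace()
    ss = np.random.SeedSequence(seed)
    param_seed, analysis_seed, *row_seeds = ss.spawn(K + 2)
    X = sample_parameter_sets(space, K, np.random.default_rng(param_seed))

    ordering_ok = pathway_ordering_ok(X)
    reject_counts = {
        "pathway_ordering": int(np.sum(~ordering_ok)),
        "rr_mean_range": 0,
        "insufficient_beats": 0,
        "undefined_entropy": 0,
    }

    rows_X: list[np.ndarray] = []
    rows_Y: list[list[float]] = []
    for i in np.flatnonzero(ordering_ok):
        row = X[i]
        mp = row_to_model_params(row, cn=space.cn)
        aa_params = AAParams(mu=row[12], sigma=row[13])
        rng = np.random.default_rng(row_seeds[i])
        intervals = sample_intervals(aa_params, n_aa, rng)
        aa = np.cumsum(intervals)
        v = simulate(aa, mp, max_beats=n_rr + 1)
        if v.size < n_rr + 1:
            reject_counts["insufficient_beats"] += 1
            continue
        rr = RRSeries.from_beat_times(v[: n_rr + 1])
        mean = rr_mean(rr)
        if not (300.0 <= mean <= 1000.0):
            reject_counts["rr_mean_range"] += 1
            continue
        try:
            sampen = rr_sample_entropy(rr, metric_cfg)
        except SampleEntropyUndefined:
            reject_counts["undefined_entropy"] += 1
            continue
        rows_X.append(row)
        rows_Y.append([mean, rr_rmssd(rr), sampen])

    n_accepted = len(rows_X)
    logger.info(
        "sensitivity study: %d/%d accepted (%.1f%%); rejections: %s",
        n_accepted, K, 100.0 * n_accepted / K, reject_counts,
    )
    if n_accepted < min_accepted:
        raise RuntimeError(
            f"only {n_accepted} parameter sets accepted (minimum {min_accepted}); "
            f"rejections: {reject_counts}"
        )
    Xa = np.vstack(rows_X)
    Ya = np.array(rows_Y)

    rng_analysis = np.random.default_rng(analysis_seed)
    S = pd.DataFrame(index=PARAM_NAMES, columns=OUTPUT_NAMES, dtype=float)
    lo_df = S.copy()
    hi_df = S.copy()
    dummy = pd.Series(index=OUTPUT_NAMES, dtype=float)
    for m_idx, out in enumerate(OUTPUT_NAMES):
        y = Ya[:, m_idx]
        dummy[out] = dummy_threshold(y, C, D, rng_analysis)
        for n_idx, name in enumerate(PARAM_NAMES):
            s, (lo, hi) = sensitivity_coefficient(
                Xa[:, n_idx], y, C, D, rng_analysis
            )
            S.loc[name, out] = s
            lo_df.loc[name, out] = lo
            hi_df.loc[name, out] = hi
    influential = S.gt(dummy, axis=1)
    return SensitivityResult(
        S=S, dummy=dummy, spread_lo=lo_df, spread_hi=hi_df,
        influential=influential, X=Xa, Y=Ya,
        n_generated=K, n_accepted=n_accepted, reject_counts=reject_counts,
    )
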