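"""Mu Suppression Index and the sensor-space inferential battery.

MSI = log10(band power in a condition / band power in the non-biological
baseline condition); negative values indicate suppression.  Group-level
inference uses one-sample t-tests against zero and a fully-within-subject
repeated-measures ANOVA with Greenhouse-Geisser correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .core import (
    DegenerateInputError,
    IncompleteDesignError,
    InvalidInputError,
    MuSuppressError,
)
from .spectral import BandPower

MSI_COLUMNS = ["subject", "session", "condition", "location", "msi"]


@dataclass
class MSITable:
    """MSI values indexed by subject x session x condition x location."""

    table: pd.DataFrame
    baseline_condition: str = "balls"

    def __post_init__(self) -> None:
        missing = set(MSI_COLUMNS) - set(self.table.columns)
        if missing:
            raise InvalidInputError(f"MSI table missing columns {sorted(missing)}")

    def subject_means(
        self,
        condition: str,
        session: str | None = None,
        locations: list[str] | None = None,
    ) -> pd.Series:
        """Per-subject MSI averaged over a location set (e.g. C3, C4, Cz)."""
        t = self.table[self.table.condition == condition]
        if session is not None:
            t = t[t.session == session]
        if locations is not None:
            t = t[t.location.isin(locations)]
        if t.empty:
            raise InvalidInputError(
                f"no MSI rows for condition={condition!r}, session={session!r}"
            )
        return t.groupby("subject", sort=True)["msi"].mean()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, baseline_condition: str = "balls") -> "MSITable":
        return cls(pd.read_csv(path, dtype={"subject": str, "session": str}),
                   baseline_condition)


@dataclass
class TestResult:
    t: float
    df: int
    p: float
    d: float
    ci: tuple[float, float]
    mean: float
    sd: float
    n: int


def compute_msi(cond_power, baseline_power):
    """log10 power ratio of a condition against the baseline condition.

    Accepts scalars, arrays, or BandPower objects; elementwise for arrays.
    """
    if isinstance(cond_power, BandPower):
        cond_power = cond_power.power
    if isinstance(baseline_power, BandPower):
        baseline_power = baseline_power.power
    cond = np.asarray(cond_power, dtype=float)
    base = np.asarray(baseline_power, dtype=float)
    if np.any(cond <= 0) or np.any(base <= 0):
        raise MuSuppressError("band powers must be strictly positive")
    out = np.log10(cond / base)
    return float(out) if out.ndim == 0 else out


def msi_ttest_zero(values) -> TestResult:
    """Two-tailed one-sample t-test of per-subject MSI means against zero.

    Also reports Cohen's d = mean/sd and the 95% CI for the mean.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise InvalidInputError("need >= 2 subjects")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero variance: t undefined")
    mean = x.mean()
    res = stats.ttest_1samp(x, 0.0, alternative="two-sided")
    df = n - 1
    half = stats.t.ppf(0.975, df) * sd / np.sqrt(n)
    return TestResult(
        t=float(res.statistic), df=df, p=float(res.pvalue), d=float(mean / sd),
        ci=(float(mean - half), float(mean + half)),
        mean=float(mean), sd=float(sd), n=n,
    )


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA (balanced, fully within-subject)
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(a: int) -> np.ndarray:
    """(a-1) x a orthonormal rows spanning the space orthogonal to ones."""
    centering = np.eye(a) - 1.0 / a
    u, s, _ = np.linalg.svd(centering)
    return u[:, : a - 1].T


def _interaction_component(data: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """Inclusion-exclusion interaction estimate for an axis subset,
    broadcast to the full array shape."""
    all_axes = tuple(range(data.ndim))
    comp = np.zeros_like(data)
    for r in range(len(axes) + 1):
        for sub in combinations(axes, r):
            other = tuple(ax for ax in all_axes if ax not in sub)
            term = data.mean(axis=other, keepdims=True) if other else data
            comp = comp + (-1.0) ** (len(axes) - r) * term
    return comp


def _gg_epsilon_and_mauchly(
    data: np.ndarray, effect_axes: tuple[int, ...]
) -> tuple[float, float, float]:
    """Greenhouse-Geisser epsilon plus Mauchly's W and p for one effect.

    Collapses over within factors not in the effect, transforms by the
    Kronecker product of per-factor orthonormal contrasts, and estimates
    epsilon from the eigenspectrum of the contrast covariance.
    """
    n = data.shape[0]
    other = tuple(ax for ax in range(1, data.ndim) if ax not in effect_axes)
    y = data.mean(axis=other) if other else data
    y = y.reshape(n, -1)
    contrast = np.ones((1, 1))
    for ax in sorted(effect_axes):
        contrast = np.kron(contrast, _orthonormal_contrasts(data.shape[ax]))
    z = y @ contrast.T
    k = z.shape[1]
    if k == 1:
        return 1.0, np.nan, np.nan
    cov = np.cov(z, rowvar=False, ddof=1)
    tr = np.trace(cov)
    tr2 = np.trace(cov @ cov)
    eps = tr**2 / (k * tr2) if tr2 > 0 else 1.0
    eps = float(np.clip(eps, 1.0 / k, 1.0))
    det = np.linalg.det(cov)
    mean_eig = tr / k
    if det <= 0 or mean_eig <= 0:
        return eps, 0.0, np.nan
    w = det / mean_eig**k
    chi2 = -(n - 1 - (2 * k**2 + k + 2) / (6.0 * k)) * np.log(w)
    df_m = k * (k + 1) // 2 - 1
    p_m = float(stats.chi2.sf(chi2, df_m)) if df_m > 0 else np.nan
    return eps, float(w), p_m


def rm_anova(
    data: np.ndarray | pd.DataFrame,
    factors: list[str],
    value: str = "msi",
    subject: str = "subject",
) -> pd.DataFrame:
    """Fully-within-subject ANOVA on a balanced complete design.

    data may be an array of shape (n_subjects, levels_1, ..., levels_k) or
    a long DataFrame with a subject column and one column per factor.
    Returns one row per effect (all main effects and interactions) with
    sums of squares, df, F, p, GG epsilon and corrected p, and partial
    eta squared; the error term for each effect is its interaction with
    subjects.
    """
    if isinstance(data, pd.DataFrame):
        arr, factors = _pivot_long(data, factors, value, subject)
    else:
        arr = np.asarray(data, dtype=float)
        if arr.ndim != len(factors) + 1:
            raise InvalidInputError(
                f"array has {arr.ndim} axes but {len(factors)} factors given"
            )
    if np.isnan(arr).any():
        raise IncompleteDesignError("design has missing cells")
    n = arr.shape[0]
    if n < 2:
        raise InvalidInputError("need >= 2 subjects")
    factor_axes = {name: i + 1 for i, name in enumerate(factors)}

    rows = []
    for order in range(1, len(factors) + 1):
        for combo in combinations(factors, order):
            axes = tuple(factor_axes[f] for f in combo)
            ss_eff = float(np.sum(_interaction_component(arr, axes) ** 2))
            ss_err = float(np.sum(_interaction_component(arr, (0,) + axes) ** 2))
            df1 = int(np.prod([arr.shape[ax] - 1 for ax in axes]))
            df2 = df1 * (n - 1)
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            f_stat = ms_eff / ms_err if ms_err > 0 else np.inf
            p = float(stats.f.sf(f_stat, df1, df2))
            eps, w, p_m = _gg_epsilon_and_mauchly(arr, axes)
            p_gg = float(stats.f.sf(f_stat, eps * df1, eps * df2))
            rows.append({
                "effect": " * ".join(combo),
                "ss": ss_eff, "ss_error": ss_err,
                "df1": df1, "df2": df2,
                "F": f_stat, "p": p,
                "eps_gg": eps, "p_gg": p_gg,
                "np2": ss_eff / (ss_eff + ss_err) if ss_eff + ss_err > 0 else np.nan,
                "mauchly_w": w, "mauchly_p": p_m,
            })
    return pd.DataFrame(rows)


def _pivot_long(
    df: pd.DataFrame, factors: list[str], value: str, subject: str
) -> tuple[np.ndarray, list[str]]:
    """Long table -> (n_subjects, levels...) array; levels in sorted order."""
    for col in [subject, value, *factors]:
        if col not in df.columns:
            raise InvalidInputError(f"column {col!r} missing")
    cell = df.groupby([subject, *factors], sort=True)[value].mean()
    subjects = sorted(df[subject].unique())
    levels = [sorted(df[f].unique()) for f in factors]
    shape = (len(subjects), *(len(lv) for lv in levels))
    expected = int(np.prod(shape))
    if len(cell) != expected:
        raise IncompleteDesignError(
            f"{len(cell)} cells present, {expected} required for a "
            "fully-crossed balanced design"
        )
    arr = cell.to_numpy(dtype=float).reshape(shape)
    return arr, factors


def median_split(first_session_msi) -> pd.Series:
    """Split subjects into 'suppresser'/'non-suppresser' halves by MSI.

    The lower half of a stable sort (strictly below the median when values
    are distinct) is labeled suppresser; ties at the median are broken by
    input order so even n always yields equal group sizes.
    """
    s = pd.Series(first_session_msi, dtype=float)
    if s.size < 2:
        raise InvalidInputError("need >= 2 subjects to split")
    order = np.argsort(s.to_numpy(), kind="stable")
    labels = np.empty(s.size, dtype=object)
    labels[order[: s.size // 2]] = "suppresser"
    labels[order[s.size // 2:]] = "non-suppresser"
    return pd.Series(labels, index=s.index, name="subgroup")


def msi_table_from_powers(
    powers: dict[tuple[str, str, str], BandPower],
    locations: list[str],
    baseline_condition: str = "balls",
) -> MSITable:
    """Build an MSITable from per-(subject, session, condition) band powers.

    The baseline power is taken from the same subject and session.
    """
    rows = []
    for (subj, sess, cond), bp in powers.items():
        if cond == baseline_condition:
            continue
        key = (subj, sess, baseline_condition)
        if key not in powers:
            raise IncompleteDesignError(
                f"baseline condition {baseline_condition!r} missing for "
                f"subject {subj}, session {sess}"
            )
        msi = compute_msi(bp, powers[key])
        for loc, value in zip(locations, np.atleast_1d(msi)):
            rows.append({"subject": subj, "session": sess, "condition": cond,
                         "location": loc, "msi": float(value)})
    return MSITable(pd.DataFrame(rows, columns=MSI_COLUMNS), baseline_condition)
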