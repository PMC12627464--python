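"""Diet-normalized offsets, hypothesis tests, and the provisioning decision rule.

The offset Δδ¹³C = δ¹³C(consumer EAA) − δ¹³C(dietary EAA) is the detection
quantity: under full dietary routing it sits near zero; microbial provisioning
predicts a conventionalized-vs-germ-free excess, with >1‰ the conventional
margin of analytical plus biological variability.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CoverageError,
    NumericalError,
    SampleSizeError,
    ValidationError,
)
from .io import EAA_PANEL, DietProfile, MeasurementTable


def compute_offsets(consumers: MeasurementTable, diet: DietProfile) -> pd.DataFrame:
    """One offset row per consumer row: value − diet mean for that amino acid.

    Returns a tidy frame with columns
    ``sample_id, group, organ, amino_acid, offset``.
    """
    df = consumers.data
    missing = sorted(set(df["amino_acid"]) - set(diet.means))
    if missing:
        raise CoverageError(
            f"diet profile lacks amino acid(s): {', '.join(missing)}"
        )
    diet_vals = df["amino_acid"].map(diet.means)
    out = df[["sample_id", "group", "organ", "amino_acid"]].copy()
    out["offset"] = df["delta13c"].to_numpy() - diet_vals.to_numpy(dtype=float)
    return out.reset_index(drop=True)


def mean_offset_per_sample(
    offsets: pd.DataFrame, panel: Sequence[str] = EAA_PANEL
) -> pd.DataFrame:
    """Arithmetic mean of the panel offsets per sample (one row per sample×organ).

    Every sample must cover the full panel; missing EAAs are an error, never
    imputed.  Columns: ``sample_id, group, organ, mean_offset``.
    """
    panel = list(panel)
    sub = offsets[offsets["amino_acid"].isin(panel)]
    counts = sub.groupby(["sample_id", "organ"])["amino_acid"].nunique()
    incomplete = counts[counts < len(panel)]
    if len(incomplete):
        sid, organ = incomplete.index[0]
        raise CoverageError(
            f"sample {sid} ({organ}) covers {int(incomplete.iloc[0])} of "
            f"{len(panel)} panel amino acids"
        )
    out = (
        sub.groupby(["sample_id", "group", "organ"], sort=False)["offset"]
        .mean()
        .rename("mean_offset")
        .reset_index()
    )
    return out


def group_summary(per_sample: pd.DataFrame) -> pd.DataFrame:
    """Group mean ± SD of per-sample mean offsets, per organ×group.

    SDs are sample SDs (ddof=1) over the per-mouse means — i.e. computed from
    raw rows, not from rounded per-EAA summaries.
    """
    return (
        per_sample.groupby(["organ", "group"])["mean_offset"]
        .agg(mean="mean", sd=lambda s: s.std(ddof=1), n="count")
        .reset_index()
    )


# ---------------------------------------------------------------------------
# Welch's t test


@dataclasses.dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int


def welch_t_from_stats(
    mean_a: float, sd_a: float, n_a: int, mean_b: float, sd_b: float, n_b: int
) -> WelchResult:
    """Welch's two-sided t test from group summary statistics.

    t = (m_a − m_b)/√(s_a²/n_a + s_b²/n_b); df by Welch–Satterthwaite
    (fractional); p from Student's t.  Printed tables can be tested without the
    raw rows this way.
    """
    if n_a < 2 or n_b < 2:
        raise SampleSizeError("Welch's t needs n >= 2 in each group")
    if not np.all(np.isfinite([mean_a, sd_a, mean_b, sd_b])):
        raise ValidationError("non-finite summary statistic")
    va, vb = sd_a**2 / n_a, sd_b**2 / n_b
    se2 = va + vb
    diff = mean_a - mean_b
    if se2 == 0.0:
        if diff == 0.0:
            # degenerate: no variance, no difference
            return WelchResult(0.0, float(n_a + n_b - 2), 1.0,
                               mean_a, mean_b, sd_a, sd_b, n_a, n_b)
        raise NumericalError("zero variance with unequal means: t undefined")
    t = diff / np.sqrt(se2)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2**2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    if not np.isfinite(df):  # variance underflow: fall back to pooled df
        df = float(n_a + n_b - 2)
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p),
                       mean_a, mean_b, sd_a, sd_b, n_a, n_b)


def welch_t(values_a: Iterable[float], values_b: Iterable[float]) -> WelchResult:
    """Welch's two-sided t test from raw observations."""
    a = np.asarray(list(values_a), dtype=float)
    b = np.asarray(list(values_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("Welch's t needs n >= 2 in each group")
    return welch_t_from_stats(
        a.mean(), a.std(ddof=1), a.size, b.mean(), b.std(ddof=1), b.size
    )


# ---------------------------------------------------------------------------
# Fligner–Killeen homogeneity of variance (delegated to scipy)


@dataclasses.dataclass(frozen=True)
class FlignerResult:
    statistic: float
    df: int
    p: float


def fligner_killeen(*groups: Iterable[float]) -> FlignerResult:
    """Fligner–Killeen test of variance homogeneity across ≥2 groups.

    Rank-based normal scores on centred absolute deviations, chi-square
    reference with (k−1) df.
    """
    if len(groups) < 2:
        raise SampleSizeError("Fligner–Killeen needs at least 2 groups")
    arrays = [np.asarray(list(g), dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise SampleSizeError("each group needs n >= 2")
    stat, p = stats.fligner(*arrays)
    return FlignerResult(float(stat), len(arrays) - 1, float(p))


# ---------------------------------------------------------------------------
# one-way MANOVA, Pillai's trace


@dataclasses.dataclass(frozen=True)
class ManovaResult:
    pillai: float
    F: float
    df_num: float
    df_den: float
    p: float
    n_groups: int
    n_responses: int


def pillai_manova(
    X: np.ndarray, labels: Sequence, ridge: float | None = None
) -> ManovaResult:
    """One-way MANOVA via Pillai's trace on response matrix X (n × p).

    Pillai V = tr(H (H+E)⁻¹) with H the between-group and E the within-group
    scatter; the standard F approximation uses s = min(p, g−1),
    m = (|p−g+1|−1)/2, n' = (N−g−p−1)/2.  A small ridge is added to H+E when it
    is numerically singular.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(list(labels), dtype=object)
    if X.ndim == 1:
        X = X[:, None]
    N, p = X.shape
    groups = sorted(set(labels))
    g = len(groups)
    if g < 2:
        raise ValidationError("MANOVA needs at least 2 groups")
    if N <= p + g:
        raise SampleSizeError(
            f"need total n > responses + groups ({N} <= {p} + {g})"
        )
    grand = X.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for lab in groups:
        sub = X[labels == lab]
        mu = sub.mean(axis=0)
        d = (mu - grand)[:, None]
        H += sub.shape[0] * (d @ d.T)
        R = sub - mu
        E += R.T @ R
    T = H + E
    if ridge is None:
        ridge = 0.0
    cond_limit = 1.0 / np.finfo(float).eps
    if ridge == 0.0 and np.linalg.cond(T) > cond_limit:
        ridge = 1e-8 * np.trace(T) / p
    if ridge:
        T = T + ridge * np.eye(p)
    try:
        V = float(np.trace(np.linalg.solve(T, H)))
    except np.linalg.LinAlgError as exc:
        raise NumericalError(f"H+E singular even after ridge: {exc}") from exc
    s = min(p, g - 1)
    m = (abs(p - g + 1) - 1) / 2.0
    n_ = (N - g - p - 1) / 2.0
    df_num = s * (2 * m + s + 1)
    df_den = s * (2 * n_ + s + 1)
    denom = s - V
    if denom <= 0:
        denom = np.finfo(float).tiny
    F = (df_den / df_num) * (V / denom)
    pval = float(stats.f.sf(F, df_num, df_den))
    return ManovaResult(V, float(F), float(df_num), float(df_den), pval, g, p)


def manova_per_organ(
    offsets: pd.DataFrame, panel: Sequence[str] = EAA_PANEL
) -> pd.DataFrame:
    """Pillai MANOVA of group on the per-sample panel offset vectors, per organ."""
    rows = []
    for organ, sub in offsets.groupby("organ"):
        wide = (
            sub[sub["amino_acid"].isin(panel)]
            .pivot_table(
                index=["sample_id", "group"],
                columns="amino_acid",
                values="offset",
            )
            .reindex(columns=list(panel))
        )
        if wide.isna().any().any():
            raise CoverageError(f"incomplete panel for MANOVA in organ {organ}")
        labels = [idx[1] for idx in wide.index]
        res = pillai_manova(wide.to_numpy(), labels)
        rows.append(
            {
                "organ": organ,
                "pillai": res.pillai,
                "F": res.F,
                "df_num": res.df_num,
                "df_den": res.df_den,
                "p": res.p,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# detection rule


@dataclasses.dataclass(frozen=True)
class ProvisioningDecision:
    """Directional threshold decision per organ.

    Microbial provisioning predicts CVZ > GF; ``detected`` requires the CVZ−GF
    difference to exceed the threshold *strictly* and in that direction.
    """

    organ: str
    mean_gf: float
    mean_cvz: float
    difference: float  # CVZ − GF
    threshold: float
    detected: bool
    direction_consistent: bool

    @classmethod
    def from_means(
        cls, organ: str, mean_gf: float, mean_cvz: float, threshold: float = 1.0
    ) -> "ProvisioningDecision":
        diff = mean_cvz - mean_gf
        direction = diff > 0
        return cls(
            organ=organ,
            mean_gf=float(mean_gf),
            mean_cvz=float(mean_cvz),
            difference=float(diff),
            threshold=float(threshold),
            detected=bool(direction and diff > threshold),
            direction_consistent=bool(direction),
        )


def provisioning_decision(
    offsets_gf: pd.DataFrame,
    offsets_cvz: pd.DataFrame,
    threshold: float = 1.0,
    panel: Sequence[str] = EAA_PANEL,
) -> list[ProvisioningDecision]:
    """Per-organ detection decisions from the two cohorts' offset tables."""
    gf = mean_offset_per_sample(offsets_gf, panel)
    cvz = mean_offset_per_sample(offsets_cvz, panel)
    organs_gf, organs_cvz = set(gf["organ"]), set(cvz["organ"])
    if organs_gf != organs_cvz:
        raise CoverageError(
            f"organ sets differ between cohorts: {sorted(organs_gf ^ organs_cvz)}"
        )
    decisions = []
    for organ in sorted(organs_gf):
        m_gf = gf.loc[gf["organ"] == organ, "mean_offset"].mean()
        m_cvz = cvz.loc[cvz["organ"] == organ, "mean_offset"].mean()
        decisions.append(
            ProvisioningDecision.from_means(organ, m_gf, m_cvz, threshold)
        )
    return decisions
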