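"""Bhattacharyya overlap in discriminant space and the two-endmember mixing model.

Overlap between two groups of LD scores is quantified with the closed-form
Bhattacharyya coefficient of their fitted Gaussians (BC = 1 identical, 0
disjoint); small per-group sizes make kernel density estimates unstable, so the
Gaussian closed form is used throughout and is exactly testable.

The mixing model inverts the two-endmember relation

    host = (1 − f) · diet + f · microbe

per EAA, using the germ-free cohort as the zero-contribution baseline so that
organ-specific trophic enrichment (present even without microbes) cancels:

    f_raw = (mean CVZ offset − mean GF offset) / (microbe − diet)

and corrects for finite tissue turnover by f = f_raw / ρ.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    ConfigurationError,
    CoverageError,
    IdentifiabilityError,
    NumericalError,
    SampleSizeError,
)
from .io import EAA_PANEL, DietProfile, EndmemberProfile


def _ensure_pd(S: np.ndarray, name: str) -> np.ndarray:
    """Symmetrize and, if needed, ridge a covariance to positive definiteness."""
    S = 0.5 * (S + S.T)
    evals = np.linalg.eigvalsh(S)
    if evals.min() <= 0:
        eps = 1e-10 * max(np.trace(S) / S.shape[0], 1.0)
        S = S + (eps - min(evals.min(), 0.0)) * np.eye(S.shape[0])
        if np.linalg.eigvalsh(S).min() <= 0:
            raise NumericalError(f"covariance {name} not positive definite")
    return S


def bhattacharyya_gaussian(
    mean_a: np.ndarray,
    cov_a: np.ndarray,
    mean_b: np.ndarray,
    cov_b: np.ndarray,
) -> float:
    """Closed-form BC between two Gaussians.

    BC = exp(−D_B) with
    D_B = ⅛ (μa−μb)ᵀ Σ̄⁻¹ (μa−μb) + ½ ln( det Σ̄ / √(det Σa det Σb) ),
    Σ̄ = (Σa+Σb)/2.
    """
    ma = np.atleast_1d(np.asarray(mean_a, dtype=float))
    mb = np.atleast_1d(np.asarray(mean_b, dtype=float))
    Sa = _ensure_pd(np.atleast_2d(np.asarray(cov_a, dtype=float)), "a")
    Sb = _ensure_pd(np.atleast_2d(np.asarray(cov_b, dtype=float)), "b")
    Sbar = 0.5 * (Sa + Sb)
    d = ma - mb
    quad = 0.125 * float(d @ np.linalg.solve(Sbar, d))
    _, ld_bar = np.linalg.slogdet(Sbar)
    _, ld_a = np.linalg.slogdet(Sa)
    _, ld_b = np.linalg.slogdet(Sb)
    logdet = 0.5 * (ld_bar - 0.5 * (ld_a + ld_b))
    return float(np.exp(-(quad + logdet)))


def bc_between_groups(
    scores_a: np.ndarray, scores_b: np.ndarray, axes: int | None = None
) -> float:
    """BC between two score clouds via per-group Gaussian fits on the first *axes*."""
    A = np.atleast_2d(np.asarray(scores_a, dtype=float))
    B = np.atleast_2d(np.asarray(scores_b, dtype=float))
    k = axes or A.shape[1]
    A, B = A[:, :k], B[:, :k]
    if A.shape[0] <= k or B.shape[0] <= k:
        raise SampleSizeError(
            f"each group needs n > {k} points for a {k}-D Gaussian fit"
        )
    Sa = np.cov(A.T) if k > 1 else np.array([[A.var(ddof=1)]])
    Sb = np.cov(B.T) if k > 1 else np.array([[B.var(ddof=1)]])
    return bhattacharyya_gaussian(A.mean(axis=0), Sa, B.mean(axis=0), Sb)


@dataclasses.dataclass
class OverlapResult:
    """Point BC plus its within-group bootstrap distribution for one group pair."""

    pair: tuple[str, str]
    point: float
    draws: np.ndarray

    @property
    def summary(self) -> dict[str, float]:
        d = self.draws
        return {
            "median": float(np.median(d)),
            "q25": float(np.quantile(d, 0.25)),
            "q75": float(np.quantile(d, 0.75)),
            "min": float(d.min()),
            "max": float(d.max()),
            "n": int(d.size),
        }


def bc_distribution(
    scores_by_group: Mapping[str, np.ndarray],
    pairs: Sequence[tuple[str, str]] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    axes: int | None = None,
) -> tuple[dict[tuple[str, str], OverlapResult], dict[str, float]]:
    """Bootstrap BC distributions per group pair plus a pooled summary.

    Members are resampled with replacement within each group and the BC
    recomputed per draw; degenerate draws are redrawn (at most 10 retries).
    The pooled summary (median, IQR, min, max, n) is over all pair×draw values.
    Deterministic given *seed*.
    """
    if n_boot < 100:
        raise ConfigurationError("n_boot must be at least 100")
    groups = {g: np.atleast_2d(np.asarray(v, dtype=float)) for g, v in scores_by_group.items()}
    if pairs is None:
        names = list(groups)
        pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    rng = np.random.default_rng(seed)
    results: dict[tuple[str, str], OverlapResult] = {}
    pooled: list[np.ndarray] = []
    for a, b in pairs:
        A, B = groups[a], groups[b]
        point = bc_between_groups(A, B, axes=axes)
        draws = np.empty(n_boot)
        for i in range(n_boot):
            for attempt in range(10):
                ia = rng.integers(0, A.shape[0], A.shape[0])
                ib = rng.integers(0, B.shape[0], B.shape[0])
                try:
                    draws[i] = bc_between_groups(A[ia], B[ib], axes=axes)
                    break
                except (NumericalError, np.linalg.LinAlgError):
                    continue
            else:
                raise NumericalError(
                    f"bootstrap draw degenerate after 10 retries for pair {(a, b)}"
                )
        results[(a, b)] = OverlapResult((a, b), point, draws)
        pooled.append(draws)
    alldraws = np.concatenate(pooled)
    pooled_summary = {
        "median": float(np.median(alldraws)),
        "q25": float(np.quantile(alldraws, 0.25)),
        "q75": float(np.quantile(alldraws, 0.75)),
        "min": float(alldraws.min()),
        "max": float(alldraws.max()),
        "n": int(alldraws.size),
    }
    return results, pooled_summary


# ---------------------------------------------------------------------------
# two-endmember mixing


def estimate_fraction(
    host_value: float,
    diet_value: float,
    microbe_value: float,
    min_separation: float = 1.0,
) -> float:
    """Raw mixing fraction f = (host − diet)/(microbe − diet).

    Below *min_separation* (‰) between the endmembers the estimator is
    declared non-identifiable.
    """
    sep = microbe_value - diet_value
    if abs(sep) <= min_separation:
        raise IdentifiabilityError(
            f"endmember separation {sep:+.3f}‰ is within the "
            f"{min_separation}‰ identifiability margin"
        )
    return float((host_value - diet_value) / sep)


@dataclasses.dataclass(frozen=True)
class OrganTurnover:
    organ: str
    rho: float

    def __post_init__(self):
        if not (0.0 <= self.rho <= 1.0):
            raise ConfigurationError(f"turnover for {self.organ} must lie in [0, 1]")


@dataclasses.dataclass(frozen=True)
class MixingEstimate:
    """Per-EAA microbial contribution for one organ."""

    organ: str
    amino_acid: str
    f: float  # reported, clipped to [0, 1]
    f_raw: float  # unclipped turnover-corrected estimate
    f_uncorrected: float  # before dividing by rho
    rho: float | None
    ci_low: float
    ci_high: float
    clipped: bool


class MixingModel:
    """Two-endmember mixing estimator with GF baseline and turnover correction.

    Parameters
    ----------
    offsets_cvz, offsets_gf
        Tidy offset frames (``compute_offsets`` output) for the two cohorts.
    diet, microbe
        Endmember profiles; per-EAA separation below ``min_separation`` makes
        that EAA non-identifiable.
    turnover
        Mapping organ → ρ (or ``OrganTurnover`` list).  ρ = 0 leaves the
        estimate uncorrected (flagged with ``rho=None``).
    """

    def __init__(
        self,
        offsets_cvz: pd.DataFrame,
        offsets_gf: pd.DataFrame,
        diet: DietProfile,
        microbe: EndmemberProfile,
        turnover: Mapping[str, float] | Sequence[OrganTurnover] | None = None,
        panel: Sequence[str] = EAA_PANEL,
        min_separation: float = 1.0,
    ):
        self.offsets_cvz = offsets_cvz
        self.offsets_gf = offsets_gf
        self.diet = diet
        self.microbe = microbe
        if turnover is None:
            turnover = {}
        if not isinstance(turnover, Mapping):
            turnover = {t.organ: t.rho for t in turnover}
        self.turnover = {k: float(v) for k, v in turnover.items()}
        self.panel = list(panel)
        self.min_separation = float(min_separation)
        organs_cvz = set(offsets_cvz["organ"])
        organs_gf = set(offsets_gf["organ"])
        if organs_cvz != organs_gf:
            raise CoverageError(
                f"cohorts cover different organs: {sorted(organs_cvz ^ organs_gf)}"
            )
        self.organs = sorted(organs_cvz)

    def _wide(self, offsets: pd.DataFrame, organ: str) -> pd.DataFrame:
        sub = offsets[
            (offsets["organ"] == organ) & (offsets["amino_acid"].isin(self.panel))
        ]
        wide = sub.pivot_table(
            index="sample_id", columns="amino_acid", values="offset"
        ).reindex(columns=self.panel)
        if wide.isna().any().any():
            raise CoverageError(f"incomplete EAA panel in organ {organ}")
        return wide

    def fit(
        self,
        n_boot: int = 1000,
        seed: int | None = None,
        ci_level: float = 0.95,
        ci_method: str = "expanded",
    ) -> "MixingResults":
        """Estimate f per organ × EAA with a mouse-resampling bootstrap CI.

        ``ci_method="expanded"`` (default) widens the percentile bootstrap
        quantiles by the t/normal calibration appropriate for small cohorts;
        ``"percentile"`` uses the plain percentile interval.
        """
        rng = np.random.default_rng(seed)
        sep = self.microbe.vector(self.panel) - self.diet.vector(self.panel)
        bad = np.abs(sep) <= self.min_separation
        if bad.any():
            names = [aa for aa, b in zip(self.panel, bad) if b]
            raise IdentifiabilityError(
                f"endmember separation within {self.min_separation}‰ for: "
                + ", ".join(names)
            )
        rows: list[MixingEstimate] = []
        for organ in self.organs:
            cvz = self._wide(self.offsets_cvz, organ).to_numpy()
            gf = self._wide(self.offsets_gf, organ).to_numpy()
            n_c, n_g = cvz.shape[0], gf.shape[0]
            rho = self.turnover.get(organ)
            if rho is not None and rho == 0.0:
                rho = None  # correction undefined; report uncorrected
            scale = sep * (rho if rho is not None else 1.0)
            f_unc = (cvz.mean(axis=0) - gf.mean(axis=0)) / sep
            f_hat = (cvz.mean(axis=0) - gf.mean(axis=0)) / scale
            ic = rng.integers(0, n_c, (n_boot, n_c))
            ig = rng.integers(0, n_g, (n_boot, n_g))
            boot = (cvz[ic].mean(axis=1) - gf[ig].mean(axis=1)) / scale
            alpha = 1.0 - ci_level
            if ci_method == "expanded":
                df = n_c + n_g - 2
                tq = stats.t.ppf(alpha / 2.0, df) * np.sqrt(n_c / (n_c - 1))
                alpha = 2.0 * stats.norm.cdf(tq)
            elif ci_method != "percentile":
                raise ConfigurationError(f"unknown ci_method '{ci_method}'")
            lo = np.quantile(boot, alpha / 2.0, axis=0)
            hi = np.quantile(boot, 1.0 - alpha / 2.0, axis=0)
            for j, aa in enumerate(self.panel):
                clipped = not (0.0 <= f_hat[j] <= 1.0)
                rows.append(
                    MixingEstimate(
                        organ=organ,
                        amino_acid=aa,
                        f=float(np.clip(f_hat[j], 0.0, 1.0)),
                        f_raw=float(f_hat[j]),
                        f_uncorrected=float(f_unc[j]),
                        rho=rho,
                        ci_low=float(lo[j]),
                        ci_high=float(hi[j]),
                        clipped=clipped,
                    )
                )
        return MixingResults(model=self, estimates=rows, n_boot=n_boot, seed=seed,
                             ci_level=ci_level, ci_method=ci_method)


@dataclasses.dataclass
class MixingResults:
    model: MixingModel
    estimates: list[MixingEstimate]
    n_boot: int
    seed: int | None
    ci_level: float
    ci_method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(e) for e in self.estimates])

    def summary(self) -> str:
        df = self.to_frame()
        lines = [
            "Two-endmember mixing estimates (microbial EAA contribution f)",
            "==============================================================",
            f"bootstrap: {self.n_boot} draws, {self.ci_method} "
            f"{100 * self.ci_level:.0f}% CI, seed={self.seed}",
            "",
            f"{'organ':>8s} {'EAA':>4s} {'f':>7s} {'raw':>7s} "
            f"{'CI low':>7s} {'CI high':>7s}  rho",
        ]
        for _, r in df.iterrows():
            rho = "--" if r["rho"] is None else f"{r['rho']:.2f}"
            flag = "*" if r["clipped"] else " "
            lines.append(
                f"{r['organ']:>8s} {r['amino_acid']:>4s} {r['f']:7.3f}{flag}"
                f"{r['f_raw']:7.3f} {r['ci_low']:7.3f} {r['ci_high']:7.3f}  {rho}"
            )
        lines.append("")
        lines.append("* reported f clipped to [0, 1]; raw retained as diagnostic")
        return "\n".join(lines)


def estimate_fraction_cohort(
    offsets_cvz: pd.DataFrame,
    offsets_gf: pd.DataFrame,
    microbe: EndmemberProfile,
    diet: DietProfile,
    turnover: Mapping[str, float] | Sequence[OrganTurnover] | None = None,
    n_boot: int = 1000,
    seed: int | None = None,
    **fit_kw,
) -> MixingResults:
    """Functional wrapper over :class:`MixingModel` (per-EAA, per-organ estimates)."""
    model = MixingModel(offsets_cvz, offsets_gf, diet, microbe, turnover=turnover)
    return model.fit(n_boot=n_boot, seed=seed, **fit_kw)
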