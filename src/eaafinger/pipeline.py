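"""End-to-end orchestration: offsets → tests → fingerprints → overlap → mixing.

``run_pipeline`` ties the stages together and writes a tidy report bundle
(CSV + JSON, plus a manifest carrying config, seed and version) to an output
directory.  All numeric report cells are produced by the single rounding
routine :func:`round_report` (round half away from zero) applied to
full-precision values — no double rounding.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .exceptions import EaaFingerError
from .fingerprint import confidence_ellipse, fingerprint_table, lda_fit, loocv
from .io import (
    EAA_PANEL,
    DietProfile,
    EndmemberProfile,
    MeasurementTable,
    TrainingSet,
    build_diet_profile,
    read_measurements,
    read_training,
)
from .offsets import (
    compute_offsets,
    group_summary,
    manova_per_organ,
    mean_offset_per_sample,
    provisioning_decision,
    welch_t,
)
from .overlap import MixingModel, bc_distribution
from .simulate import DEFAULT_MICROBE, DEFAULT_TURNOVER, TrainingSimConfig, simulate_training

logger = logging.getLogger(__name__)


def round_report(x: float, decimals: int = 1) -> float:
    """Round half away from zero at *decimals* places (reporting convention)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def significance_stars(p: float) -> str:
    """Star codes at the conventional levels: NS, * <0.05, ** <0.01, *** <0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "NS"


def render_table1(summary: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Format an offset summary as the familiar per-organ table.

    *summary* needs columns ``organ, group, amino_acid, mean, sd`` and
    optionally ``p``; the output has one row per organ × group with
    "mean ± sd" cells per EAA, an ``Avg`` cell, and star rows where p values
    are present.
    """
    rows = []
    for organ in summary["organ"].unique():
        org = summary[summary["organ"] == organ]
        for group in org["group"].unique():
            sub = org[org["group"] == group].set_index("amino_acid")
            cells = {"organ": organ, "row": group}
            for aa in EAA_PANEL:
                m = round_report(sub.loc[aa, "mean"], decimals)
                s = round_report(sub.loc[aa, "sd"], decimals)
                cells[aa] = f"{m} ± {s}"
            if "avg_mean" in sub.columns:
                am = round_report(sub["avg_mean"].iloc[0], decimals)
                asd = round_report(sub["avg_sd"].iloc[0], decimals)
                cells["Avg"] = f"{am} ± {asd}"
            else:
                cells["Avg"] = str(
                    round_report(float(sub.loc[list(EAA_PANEL), "mean"].mean()), decimals)
                )
            rows.append(cells)
        if "p" in org.columns:
            pr = org.drop_duplicates("amino_acid").set_index("amino_acid")["p"]
            rows.append(
                {"organ": organ, "row": "P value"}
                | {aa: f"{pr[aa]:.3f}" for aa in EAA_PANEL}
                | {"Avg": "NA"}
            )
            rows.append(
                {"organ": organ, "row": "Sign. level"}
                | {aa: significance_stars(pr[aa]) for aa in EAA_PANEL}
                | {"Avg": "NA"}
            )
    return pd.DataFrame(rows)


@dataclasses.dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    measurements: str | Path | MeasurementTable
    training: str | Path | TrainingSet | None = None
    endmember: EndmemberProfile = DEFAULT_MICROBE
    diet_label: str = "diet"
    group_gf: str = "GF"
    group_cvz: str = "CVZ"
    turnover: dict[str, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TURNOVER)
    )
    threshold: float = 1.0
    n_boot: int = 1000
    seed: int = 0
    out_dir: str | Path = "results"
    decimals: int = 1

    def __post_init__(self):
        if self.threshold <= 0:
            raise EaaFingerError("threshold must be > 0")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except EaaFingerError as exc:
                raise EaaFingerError(f"stage '{name}': {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle.

    Returns a dict with the in-memory results (offsets, summaries, scores,
    decisions, mixing estimates, BC summaries) and writes CSV/JSON files plus
    ``manifest.json`` under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    table = (
        config.measurements
        if isinstance(config.measurements, MeasurementTable)
        else read_measurements(config.measurements)
    )
    diet = _stage("diet_profile")(build_diet_profile)(table, config.diet_label)
    consumers = table.subset(group=[config.group_gf, config.group_cvz])
    offsets = _stage("offsets")(compute_offsets)(consumers, diet)
    offsets.to_csv(out / "offsets.csv", index=False)

    off_gf = offsets[offsets["group"] == config.group_gf]
    off_cvz = offsets[offsets["group"] == config.group_cvz]

    # Table-1-style summary with Welch tests per organ × EAA
    summary_rows = []
    for organ in sorted(set(offsets["organ"])):
        for aa in EAA_PANEL:
            a = off_cvz[(off_cvz["organ"] == organ) & (off_cvz["amino_acid"] == aa)][
                "offset"
            ]
            b = off_gf[(off_gf["organ"] == organ) & (off_gf["amino_acid"] == aa)][
                "offset"
            ]
            w = welch_t(a, b)
            for group, vals in ((config.group_gf, b), (config.group_cvz, a)):
                summary_rows.append(
                    {
                        "organ": organ,
                        "group": group,
                        "amino_acid": aa,
                        "mean": float(vals.mean()),
                        "sd": float(vals.std(ddof=1)),
                        "n": int(len(vals)),
                        "t": w.t,
                        "df": w.df,
                        "p": w.p,
                        "stars": significance_stars(w.p),
                    }
                )
    summary = pd.DataFrame(summary_rows)
    per_sample = mean_offset_per_sample(offsets)
    gsum = group_summary(per_sample)
    summary = summary.merge(
        gsum.rename(columns={"mean": "avg_mean", "sd": "avg_sd", "n": "avg_n"}),
        on=["organ", "group"],
    )
    summary.to_csv(out / "table1_summary.csv", index=False)
    render_table1(summary, config.decimals).to_csv(out / "table1_rendered.csv", index=False)

    manova = _stage("manova")(manova_per_organ)(offsets)
    manova.to_csv(out / "manova.csv", index=False)

    # fingerprinting
    if config.training is None:
        training = simulate_training(TrainingSimConfig(seed=config.seed))
    elif isinstance(config.training, TrainingSet):
        training = config.training
    else:
        training = read_training(config.training)
    lda = _stage("lda_fit")(lda_fit)(training)
    cv = loocv(training)
    (out / "loocv.json").write_text(
        json.dumps(
            {"accuracy": cv["accuracy"], "per_class": cv["per_class"], "n": cv["n"]},
            indent=2,
        )
    )
    lda.to_json(out / "lda_model.json")

    fps = fingerprint_table(consumers)
    scores = lda.transform(fps.to_numpy())
    score_df = pd.DataFrame(
        scores, columns=[f"LD{i + 1}" for i in range(scores.shape[1])]
    )
    score_df.insert(0, "organ", [ix[2] for ix in fps.index])
    score_df.insert(0, "group", [ix[1] for ix in fps.index])
    score_df.insert(0, "sample_id", [ix[0] for ix in fps.index])
    train_scores = lda.transform(training.X)
    for cls in lda.classes:
        cls_scores = train_scores[training.labels == cls]
        sdf = pd.DataFrame(
            cls_scores, columns=[f"LD{i + 1}" for i in range(scores.shape[1])]
        )
        sdf.insert(0, "organ", "reference")
        sdf.insert(0, "group", cls)
        sdf.insert(0, "sample_id", list(training.taxa[training.labels == cls]))
        score_df = pd.concat([score_df, sdf], ignore_index=True)
    score_df.to_csv(out / "ld_scores.csv", index=False)

    ellipses = {}
    for cls in lda.classes:
        ell = confidence_ellipse(train_scores[training.labels == cls, :2], 0.95)
        ellipses[cls] = dataclasses.asdict(ell)
    (out / "ellipses.json").write_text(json.dumps(ellipses, indent=2))

    # overlap: pooled GF-vs-CVZ (headline) plus per-organ pairs
    scores_by_group = {
        config.group_gf: scores[[ix[1] == config.group_gf for ix in fps.index]],
        config.group_cvz: scores[[ix[1] == config.group_cvz for ix in fps.index]],
    }
    _, pooled = _stage("overlap")(bc_distribution)(
        scores_by_group,
        pairs=[(config.group_gf, config.group_cvz)],
        n_boot=config.n_boot,
        seed=config.seed,
    )
    per_organ = {}
    for organ in sorted({ix[2] for ix in fps.index}):
        sel_g = [ix[1] == config.group_gf and ix[2] == organ for ix in fps.index]
        sel_c = [ix[1] == config.group_cvz and ix[2] == organ for ix in fps.index]
        by = {config.group_gf: scores[sel_g], config.group_cvz: scores[sel_c]}
        try:
            _, s = bc_distribution(
                by,
                pairs=[(config.group_gf, config.group_cvz)],
                n_boot=max(config.n_boot // 4, 100),
                seed=config.seed,
            )
            per_organ[organ] = s
        except EaaFingerError as exc:
            per_organ[organ] = {"error": str(exc)}
    (out / "bc_summary.json").write_text(
        json.dumps({"pooled_GF_vs_CVZ": pooled, "per_organ": per_organ}, indent=2)
    )

    # mixing
    mix = _stage("mixing")(
        lambda: MixingModel(
            off_cvz, off_gf, diet, config.endmember, turnover=config.turnover
        ).fit(n_boot=config.n_boot, seed=config.seed)
    )()
    mix.to_frame().to_csv(out / "mixing.csv", index=False)

    decisions = _stage("decision")(provisioning_decision)(
        off_gf, off_cvz, threshold=config.threshold
    )
    dec_df = pd.DataFrame([dataclasses.asdict(d) for d in decisions])
    dec_df.to_csv(out / "decisions.csv", index=False)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "threshold": config.threshold,
        "n_boot": config.n_boot,
        "groups": [config.group_gf, config.group_cvz],
        "turnover": config.turnover,
        "endmember": {"label": config.endmember.label,
                      "means": dict(config.endmember.means)},
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return {
        "offsets": offsets,
        "summary": summary,
        "manova": manova,
        "scores": score_df,
        "loocv": cv,
        "ellipses": ellipses,
        "bc_pooled": pooled,
        "bc_per_organ": per_organ,
        "mixing": mix,
        "decisions": decisions,
        "manifest": manifest,
    }
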