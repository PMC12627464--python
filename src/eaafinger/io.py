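"""Domain types and delimited-text I/O for compound-specific amino acid isotope data.

All tables are long ("tidy"): one row per measured amino acid per sample, with
δ¹³C in per-mil (‰) vs VPDB.  Wide per-sample matrices are derived on demand and
never stored.  Values are carried at full floating precision; rounding happens
only in reporting (:func:`eaafinger.pipeline.round_report`).
"""

from __future__ import annotations

import dataclasses
from collections.abc import Iterable, Mapping
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import (
    CoverageError,
    ParseError,
    SchemaError,
    ValidationError,
)

#: The canonical essential amino acid panel used for fingerprinting, in
#: reporting order: isoleucine, leucine, lysine, phenylalanine, threonine,
#: valine.
EAA_PANEL: tuple[str, ...] = ("Ile", "Leu", "Lys", "Phe", "Thr", "Val")

#: Common non-essential codes accepted in measurement tables (open set; these
#: pass through the offset machinery but are excluded from fingerprints).
NEAA_CODES: frozenset[str] = frozenset(
    {"Ala", "Asp", "Asx", "Glu", "Glx", "Gly", "Pro", "Ser", "Tyr", "Arg", "His", "Met"}
)

MEASUREMENT_COLUMNS = ("sample_id", "group", "organ", "amino_acid", "delta13c")

#: Default column-name mapping (canonical name -> column name in the file).
DEFAULT_DIALECT: dict[str, str] = {c: c for c in MEASUREMENT_COLUMNS} | {
    "replicate": "replicate"
}


def is_essential(code: str) -> bool:
    """True if *code* is one of the six canonical EAAs."""
    return code in EAA_PANEL


@dataclasses.dataclass(frozen=True)
class AminoAcid:
    """A short amino-acid code plus its essentiality flag."""

    code: str
    essential: bool = dataclasses.field(default=False)

    @classmethod
    def from_code(cls, code: str) -> "AminoAcid":
        return cls(code=code, essential=is_essential(code))


class MeasurementTable:
    """Long-format δ¹³C observations with validation.

    Parameters
    ----------
    data
        DataFrame with columns ``sample_id, group, organ, amino_acid, delta13c``
        and optionally ``replicate``.
    metadata
        Free-form key/value metadata; ``units`` defaults to ``"permil_VPDB"``.
    """

    def __init__(self, data: pd.DataFrame, metadata: Mapping[str, str] | None = None):
        self.data = self._validate(data)
        self.metadata = {"units": "permil_VPDB"} | dict(metadata or {})

    @staticmethod
    def _validate(data: pd.DataFrame) -> pd.DataFrame:
        missing = [c for c in MEASUREMENT_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        df = data.copy()
        vals = pd.to_numeric(df["delta13c"], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        if bad.any():
            rows = df.index[bad].tolist()[:5]
            raise ParseError(f"non-finite/non-numeric delta13c at row(s) {rows}")
        df["delta13c"] = vals.astype(float)
        if "replicate" not in df.columns:
            df["replicate"] = 1
        key = ["sample_id", "organ", "amino_acid", "replicate"]
        dup = df.duplicated(subset=key)
        if dup.any():
            first = df.loc[dup, key].iloc[0].tolist()
            raise ValidationError(f"duplicate measurement key {first}")
        return df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self.data[list(MEASUREMENT_COLUMNS) + ["replicate"]]
        b = other.data[list(MEASUREMENT_COLUMNS) + ["replicate"]]
        return a.equals(b)

    def subset(self, **selectors: str | Iterable[str]) -> "MeasurementTable":
        """Rows matching every column=value (or column=iterable) selector."""
        df = self.data
        for col, val in selectors.items():
            if isinstance(val, str):
                df = df[df[col] == val]
            else:
                df = df[df[col].isin(list(val))]
        return MeasurementTable(df, self.metadata)

    def to_wide(
        self, panel: Iterable[str] = EAA_PANEL, require_complete: bool = True
    ) -> pd.DataFrame:
        """Per-sample wide matrix over *panel*, indexed by (sample_id, group, organ).

        Replicates are averaged.  With ``require_complete`` (the default) any
        sample missing a panel amino acid raises :class:`CoverageError` —
        fingerprinting never imputes.
        """
        panel = list(panel)
        df = self.data[self.data["amino_acid"].isin(panel)]
        wide = (
            df.groupby(["sample_id", "group", "organ", "amino_acid"], sort=False)[
                "delta13c"
            ]
            .mean()
            .unstack("amino_acid")
        )
        missing_cols = [aa for aa in panel if aa not in wide.columns]
        if missing_cols and require_complete:
            raise CoverageError(
                f"amino acid(s) absent from table: {', '.join(missing_cols)}"
            )
        wide = wide.reindex(columns=panel)
        if require_complete and wide.isna().any().any():
            bad = wide.index[wide.isna().any(axis=1)][0]
            raise CoverageError(f"sample {bad} is missing panel amino acids")
        return wide


@dataclasses.dataclass(frozen=True)
class DietProfile:
    """Per-amino-acid mean dietary δ¹³C (‰) with replicate counts."""

    means: Mapping[str, float]
    n_replicates: Mapping[str, int] = dataclasses.field(default_factory=dict)
    label: str = "diet"

    def __post_init__(self):
        missing = [aa for aa in EAA_PANEL if aa not in self.means]
        if missing:
            raise CoverageError(
                f"diet profile lacks EAA(s): {', '.join(missing)}"
            )
        if not all(np.isfinite(list(self.means.values()))):
            raise ValidationError("diet profile contains non-finite values")

    def vector(self, panel: Iterable[str] = EAA_PANEL) -> np.ndarray:
        return np.array([self.means[aa] for aa in panel], dtype=float)


@dataclasses.dataclass(frozen=True)
class EndmemberProfile:
    """A pure-source δ¹³C signature (e.g. gut bacteria) on the EAA panel."""

    label: str
    means: Mapping[str, float]
    spread: Mapping[str, float] | None = None

    def __post_init__(self):
        if not all(np.isfinite(list(self.means.values()))):
            raise ValidationError(f"endmember '{self.label}' has non-finite values")

    def vector(self, panel: Iterable[str] = EAA_PANEL) -> np.ndarray:
        try:
            return np.array([self.means[aa] for aa in panel], dtype=float)
        except KeyError as exc:
            raise CoverageError(
                f"endmember '{self.label}' lacks amino acid {exc.args[0]}"
            ) from exc


class TrainingSet:
    """Labelled mean-centred fingerprints for the classifier groups.

    ``X`` is (n_samples, n_panel) mean-centred per row; ``labels`` are class
    names (bacteria / fungi / plants in the canonical three-class model);
    ``taxa`` identify the reference organisms.
    """

    def __init__(
        self,
        X: np.ndarray,
        labels: Iterable[str],
        taxa: Iterable[str] | None = None,
        panel: Iterable[str] = EAA_PANEL,
        center: bool = False,
    ):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(list(labels), dtype=object)
        panel = tuple(panel)
        if X.ndim != 2 or X.shape[1] != len(panel):
            raise ValidationError(
                f"fingerprint matrix must be (n, {len(panel)}); got {X.shape}"
            )
        if len(labels) != X.shape[0]:
            raise ValidationError("labels length does not match fingerprint count")
        if not np.all(np.isfinite(X)):
            raise ValidationError("training fingerprints contain non-finite values")
        if center:
            X = X - X.mean(axis=1, keepdims=True)
        elif np.abs(X.sum(axis=1)).max() > 1e-9:
            raise ValidationError(
                "fingerprints are not mean-centred (row sums exceed 1e-9); "
                "pass center=True to centre raw profiles"
            )
        if len(set(labels)) < 2:
            raise ValidationError("training set needs at least 2 classes")
        self.X = X
        self.labels = labels
        self.taxa = (
            np.asarray(list(taxa), dtype=object)
            if taxa is not None
            else np.array([f"ref{i}" for i in range(len(labels))], dtype=object)
        )
        self.panel = panel

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.labels))

    @property
    def class_counts(self) -> dict[str, int]:
        return {c: int((self.labels == c).sum()) for c in self.classes}

    def __len__(self) -> int:
        return self.X.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=list(self.panel))
        df.insert(0, "class", self.labels)
        df.insert(0, "taxon", self.taxa)
        return df


# ---------------------------------------------------------------------------
# readers / writers


def read_measurements(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> MeasurementTable:
    """Read a long-format measurement CSV.

    ``dialect`` maps canonical column names to the file's header names, so
    external tables can be ingested without editing the file.
    """
    d = DEFAULT_DIALECT | dict(dialect or {})
    raw = pd.read_csv(path)
    rename = {}
    for canonical in MEASUREMENT_COLUMNS:
        src = d[canonical]
        if src not in raw.columns:
            raise SchemaError(
                f"column '{src}' (for '{canonical}') not found in {path}"
            )
        rename[src] = canonical
    if d.get("replicate") in raw.columns:
        rename[d["replicate"]] = "replicate"
    df = raw.rename(columns=rename)
    keep = [c for c in list(MEASUREMENT_COLUMNS) + ["replicate"] if c in df.columns]
    return MeasurementTable(df[keep])


def write_measurements(table: MeasurementTable, path: str | Path) -> None:
    """Write a validated table as CSV (header, stable column order, full precision)."""
    cols = list(MEASUREMENT_COLUMNS) + ["replicate"]
    table.data[cols].to_csv(path, index=False)


def read_training(path: str | Path, center: bool = True) -> TrainingSet:
    """Read a training CSV: columns ``taxon, class`` then one column per EAA code.

    Raw (uncentred) reference profiles are mean-centred on load by default,
    matching the fingerprint definition.
    """
    df = pd.read_csv(path)
    for col in ("taxon", "class"):
        if col not in df.columns:
            raise SchemaError(f"training file lacks column '{col}'")
    missing = [aa for aa in EAA_PANEL if aa not in df.columns]
    if missing:
        raise CoverageError(f"training file lacks EAA column(s): {', '.join(missing)}")
    X = df[list(EAA_PANEL)].to_numpy(dtype=float)
    return TrainingSet(X, df["class"], taxa=df["taxon"], center=center)


def write_training(ts: TrainingSet, path: str | Path) -> None:
    ts.to_frame().to_csv(path, index=False)


def build_diet_profile(
    table: MeasurementTable, diet_label: str = "diet", by: str = "organ"
) -> DietProfile:
    """Per-EAA arithmetic mean over diet replicates.

    ``diet_label`` selects rows where column *by* (default ``organ``) equals it.
    """
    rows = table.data[table.data[by] == diet_label]
    means: dict[str, float] = {}
    ns: dict[str, int] = {}
    for aa in EAA_PANEL:
        sub = rows[rows["amino_acid"] == aa]
        if len(sub) == 0:
            raise CoverageError(f"no diet measurement for amino acid {aa}")
        means[aa] = float(sub["delta13c"].mean())
        ns[aa] = int(len(sub))
    # carry non-essential codes when present (pass-through offsets)
    for aa in sorted(set(rows["amino_acid"]) - set(EAA_PANEL)):
        sub = rows[rows["amino_acid"] == aa]
        means[aa] = float(sub["delta13c"].mean())
        ns[aa] = int(len(sub))
    return DietProfile(means=means, n_replicates=ns, label=diet_label)
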