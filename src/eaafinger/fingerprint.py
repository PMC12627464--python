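"""δ¹³C-EAA fingerprinting: mean-centring, calibration, and linear discriminant analysis.

A fingerprint is a sample's EAA δ¹³C vector minus its own mean — a zero-sum
pattern diagnostic of the biosynthetic source domain (bacteria, fungi, plants)
and invariant to any bulk isotopic shift of the sample.  The discriminant model
is fitted from scratch (class means, pooled within-class covariance, the
generalized between/within eigenproblem) in the style of classical discriminant
function analysis, so its internals — scalings, priors, score-space geometry —
are fully inspectable and serialisable.

Because fingerprints are zero-sum, their within-class scatter is singular along
the all-ones direction; the fit works in the non-degenerate subspace and only
falls back to a ridge when between-class signal would otherwise be lost.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CoverageError,
    NumericalError,
    SampleSizeError,
    ValidationError,
)
from .io import EAA_PANEL, MeasurementTable, TrainingSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class Fingerprint:
    """A mean-centred per-EAA pattern for one sample."""

    sample_id: str
    values: Mapping[str, float]
    label: str | None = None

    def vector(self, panel: Sequence[str] = EAA_PANEL) -> np.ndarray:
        return np.array([self.values[aa] for aa in panel], dtype=float)


def mean_center(values, panel: Sequence[str] = EAA_PANEL) -> np.ndarray:
    """Centre a per-EAA vector (array-like or mapping over *panel*) to zero mean."""
    if isinstance(values, Mapping):
        missing = [aa for aa in panel if aa not in values]
        if missing:
            raise CoverageError(f"missing EAA(s): {', '.join(missing)}")
        x = np.array([values[aa] for aa in panel], dtype=float)
    else:
        x = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite value in fingerprint input")
    return x - x.mean()


def fingerprint_table(
    table: MeasurementTable, panel: Sequence[str] = EAA_PANEL
) -> pd.DataFrame:
    """Mean-centred wide matrix (rows indexed by sample_id, group, organ)."""
    wide = table.to_wide(panel=panel, require_complete=True)
    return wide.sub(wide.mean(axis=1), axis=0)


def calibrate_interlab(
    table: MeasurementTable,
    reference_measured: Mapping[str, float],
    reference_known: Mapping[str, float],
) -> MeasurementTable:
    """Apply the per-EAA additive correction (known − measured) to all rows.

    The two reference panels must cover the same amino acids; table rows whose
    amino acid is outside the reference panel pass through unchanged.
    """
    if set(reference_measured) != set(reference_known):
        raise CoverageError("reference panels do not align")
    corr = {aa: reference_known[aa] - reference_measured[aa] for aa in reference_known}
    df = table.data.copy()
    df["delta13c"] = df["delta13c"] + df["amino_acid"].map(corr).fillna(0.0)
    return MeasurementTable(df, table.metadata | {"calibrated": "interlab"})


# ---------------------------------------------------------------------------
# linear discriminant model


class LinearDiscriminant:
    """Discriminant model over labelled fingerprints (statsmodels-style).

    Construct from arrays or a :class:`~eaafinger.io.TrainingSet`, then call
    :meth:`fit` for a :class:`LDAResults`.
    """

    def __init__(
        self,
        X: np.ndarray,
        labels: Sequence[str],
        priors: Mapping[str, float] | str = "proportions",
        panel: Sequence[str] | None = None,
    ):
        self.X = np.asarray(X, dtype=float)
        self.labels = np.asarray(list(labels), dtype=object)
        if self.X.ndim != 2 or self.X.shape[0] != len(self.labels):
            raise ValidationError("X must be (n_samples, n_features) matching labels")
        self.classes = sorted(set(self.labels))
        if len(self.classes) < 2:
            raise ValidationError("need at least 2 classes")
        for c in self.classes:
            if (self.labels == c).sum() < 2:
                raise SampleSizeError(f"class '{c}' has n < 2")
        self.panel = tuple(panel) if panel is not None else None
        if priors == "proportions":
            n = len(self.labels)
            self.priors = {c: (self.labels == c).sum() / n for c in self.classes}
        elif priors == "uniform":
            self.priors = {c: 1.0 / len(self.classes) for c in self.classes}
        else:
            tot = sum(priors[c] for c in self.classes)
            self.priors = {c: priors[c] / tot for c in self.classes}

    @classmethod
    def from_training_set(
        cls, ts: TrainingSet, priors: Mapping[str, float] | str = "proportions"
    ) -> "LinearDiscriminant":
        return cls(ts.X, ts.labels, priors=priors, panel=ts.panel)

    def fit(
        self, n_components: int | None = None, ridge: float | None = None
    ) -> "LDAResults":
        """Fit class means, pooled within-class covariance and discriminants.

        The scaling matrix is normalized so projected within-class covariance
        is the identity; discriminants are ordered by decreasing between-class
        separation and sign-fixed so each one's largest-magnitude loading is
        positive.
        """
        X, labels = self.X, self.labels
        N, p = X.shape
        g = len(self.classes)
        means = np.stack([X[labels == c].mean(axis=0) for c in self.classes])
        ns = np.array([(labels == c).sum() for c in self.classes])
        xbar = X.mean(axis=0)

        W = np.zeros((p, p))
        for c, mu in zip(self.classes, means):
            R = X[labels == c] - mu
            W += R.T @ R
        W /= N - g
        B = np.zeros((p, p))
        for nk, mu in zip(ns, means):
            d = (mu - xbar)[:, None]
            B += nk * (d @ d.T)

        evals, U = np.linalg.eigh(W)
        tol = max(evals.max(), 0.0) * 1e-10
        keep = evals > tol
        if not keep.all():
            # between-class signal in the within-null space cannot be whitened;
            # ridge only if truncation would discard it
            U_null = U[:, ~keep]
            lost = float(np.trace(U_null.T @ B @ U_null))
            if lost > 1e-9 * max(np.trace(B), np.finfo(float).tiny):
                eps = (ridge if ridge is not None else 1e-8) * np.trace(W) / p
                logger.warning(
                    "within-class scatter singular with between-class signal in "
                    "its null space; applying ridge %.3e", eps,
                )
                W = W + eps * np.eye(p)
                evals, U = np.linalg.eigh(W)
                keep = np.ones(p, dtype=bool)
        Ur = U[:, keep]
        Dr = evals[keep]
        if Dr.min() <= 0:
            raise NumericalError("within-class covariance not positive on subspace")
        whiten = Ur / np.sqrt(Dr)  # (p, r): whiten.T @ W @ whiten = I
        Bw = whiten.T @ B @ whiten
        bvals, V = np.linalg.eigh(Bw)
        order = np.argsort(bvals)[::-1]
        max_rank = min(g - 1, whiten.shape[1])
        k = max_rank if n_components is None else min(n_components, max_rank)
        V = V[:, order[:k]]
        bvals = np.maximum(bvals[order[:k]], 0.0)
        scaling = whiten @ V  # (p, k)
        # sign convention: largest-|loading| entry positive per discriminant
        for j in range(scaling.shape[1]):
            i = np.argmax(np.abs(scaling[:, j]))
            if scaling[i, j] < 0:
                scaling[:, j] = -scaling[:, j]
        return LDAResults(
            model=self,
            classes=list(self.classes),
            priors=dict(self.priors),
            class_means=means,
            xbar=xbar,
            within_cov=W,
            scaling=scaling,
            separation=bvals / max(N - g, 1),
            panel=self.panel,
        )


@dataclasses.dataclass
class LDAResults:
    """Fitted discriminant space: projection, classification, ellipses, overlap input."""

    model: LinearDiscriminant | None
    classes: list[str]
    priors: dict[str, float]
    class_means: np.ndarray  # (g, p) in fingerprint space
    xbar: np.ndarray  # (p,)
    within_cov: np.ndarray  # (p, p) pooled
    scaling: np.ndarray  # (p, k)
    separation: np.ndarray  # (k,) between-class eigenvalues (descending)
    panel: tuple[str, ...] | None = None

    @property
    def n_components(self) -> int:
        return self.scaling.shape[1]

    @property
    def class_scores(self) -> np.ndarray:
        """Class centroids in discriminant space, (g, k)."""
        return (self.class_means - self.xbar) @ self.scaling

    def _check_panel(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.scaling.shape[0]:
            raise CoverageError(
                f"sample panel width {X.shape[1]} does not match training "
                f"width {self.scaling.shape[0]}"
            )
        return X

    def transform(self, X) -> np.ndarray:
        """Project samples into LD space: (X − training mean) @ scaling."""
        X = self._check_panel(X)
        return (X - self.xbar) @ self.scaling

    def classify(self, X) -> tuple[np.ndarray, np.ndarray]:
        """Hard labels and class posteriors for samples.

        Gaussian class-conditional densities with shared (identity) covariance
        in score space; posteriors ∝ prior × density; ties resolved toward the
        first class in label order.
        """
        Z = self.transform(X)
        C = self.class_scores
        d2 = ((Z[:, None, :] - C[None, :, :]) ** 2).sum(axis=2)  # (n, g)
        logprior = np.log([self.priors[c] for c in self.classes])
        logpost = -0.5 * d2 + logprior
        logpost -= logpost.max(axis=1, keepdims=True)
        post = np.exp(logpost)
        post /= post.sum(axis=1, keepdims=True)
        labels = np.empty(post.shape[0], dtype=object)
        for i, row in enumerate(post):
            winners = np.flatnonzero(row >= row.max() - 1e-12)
            labels[i] = self.classes[winners[0]]
        return labels, post

    def summary(self) -> str:
        lines = [
            "Linear discriminant analysis",
            "============================",
            f"classes: {', '.join(self.classes)}",
            f"priors:  " + ", ".join(f"{c}={self.priors[c]:.3f}" for c in self.classes),
            f"retained discriminants: {self.n_components}",
            "between-class separation (eigenvalues): "
            + ", ".join(f"{v:.4g}" for v in self.separation),
            "",
            "discriminant loadings:",
        ]
        names = list(self.panel) if self.panel else [
            f"x{i}" for i in range(self.scaling.shape[0])
        ]
        for i, name in enumerate(names):
            lines.append(
                f"  {name:>4s}  "
                + "  ".join(f"{self.scaling[i, j]: .4f}" for j in range(self.n_components))
            )
        return "\n".join(lines)

    # -- persistence -------------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "classes": self.classes,
            "priors": self.priors,
            "class_means": self.class_means.tolist(),
            "xbar": self.xbar.tolist(),
            "within_cov": self.within_cov.tolist(),
            "scaling": self.scaling.tolist(),
            "separation": self.separation.tolist(),
            "panel": list(self.panel) if self.panel else None,
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LDAResults":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            model=None,
            classes=d["classes"],
            priors=d["priors"],
            class_means=np.array(d["class_means"]),
            xbar=np.array(d["xbar"]),
            within_cov=np.array(d["within_cov"]),
            scaling=np.array(d["scaling"]),
            separation=np.array(d["separation"]),
            panel=tuple(d["panel"]) if d["panel"] else None,
        )


def lda_fit(
    training: TrainingSet,
    priors: Mapping[str, float] | str = "proportions",
    n_components: int | None = None,
) -> LDAResults:
    """Convenience wrapper: fit the discriminant model on a training set."""
    return LinearDiscriminant.from_training_set(training, priors=priors).fit(
        n_components=n_components
    )


def loocv(
    training: TrainingSet, priors: Mapping[str, float] | str = "proportions"
) -> dict:
    """Leave-one-out cross-validation of the discriminant classifier.

    Refits excluding each sample in turn and classifies it.  Returns overall
    accuracy, per-class accuracy, and a confusion table (rows true, cols
    predicted).
    """
    X, y = training.X, training.labels
    n = len(y)
    for c in sorted(set(y)):
        if (y == c).sum() < 3:
            raise SampleSizeError(
                f"LOOCV needs n >= 3 per class; class '{c}' too small"
            )
    classes = sorted(set(y))
    confusion = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        res = LinearDiscriminant(X[mask], y[mask], priors=priors).fit()
        pred, _ = res.classify(X[i])
        confusion.loc[y[i], pred[0]] += 1
    correct = np.diag(confusion.to_numpy()).sum()
    per_class = {
        c: float(confusion.loc[c, c] / confusion.loc[c].sum()) for c in classes
    }
    return {
        "accuracy": float(correct / n),
        "per_class": per_class,
        "confusion": confusion,
        "n": int(n),
    }


# ---------------------------------------------------------------------------
# confidence ellipses


@dataclasses.dataclass(frozen=True)
class Ellipse:
    """A coverage ellipse of a 2-D Gaussian fit (half-axis lengths)."""

    center: tuple[float, float]
    semimajor: float
    semiminor: float
    angle_deg: float  # orientation of the major axis, counter-clockwise from x
    level: float


def confidence_ellipse(scores: np.ndarray, level: float = 0.95) -> Ellipse:
    """Coverage ellipse from the sample mean and covariance of 2-D scores.

    Axis half-lengths are sqrt(eigenvalue × chi²₂ quantile at *level*).
    """
    if not (0.0 < level < 1.0):
        raise ValidationError("coverage level must lie in (0, 1)")
    Z = np.asarray(scores, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != 2:
        raise ValidationError("scores must be (n, 2)")
    if Z.shape[0] < 3:
        raise SampleSizeError("need n >= 3 points for an ellipse")
    mu = Z.mean(axis=0)
    S = np.cov(Z.T)
    evals, evecs = np.linalg.eigh(S)
    if evals.min() <= 0:
        raise NumericalError(
            "degenerate score covariance (zero variance direction); ellipse undefined"
        )
    q = stats.chi2.ppf(level, df=2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])))
    return Ellipse(
        center=(float(mu[0]), float(mu[1])),
        semimajor=float(np.sqrt(evals[0] * q)),
        semiminor=float(np.sqrt(evals[1] * q)),
        angle_deg=angle,
        level=level,
    )
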