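"""Probabilistic organelle-targeting classifier for TA proteins.

The model: a 3-class support vector machine on two features —
net tail charge and TMD GRAVY — with an RBF kernel, one-vs-one binary
machines, Platt sigmoid calibration of each pairwise margin and
pairwise coupling of the calibrated probabilities (the libsvm
probability machinery).  Features are standardized on the training set.
Default hyperparameters are the libsvm/e1071 defaults for two features:
``C = 1``, ``gamma = 1 / n_features = 0.5``.

API follows the model/results convention of statistical modelling
packages: build a :class:`TargetingModel` from data (arrays, a
DataFrame, or labeled dataset entries), call :meth:`~TargetingModel.fit`
to obtain a :class:`TargetingResults` carrying the fitted parameters,
diagnostics (in-sample misclassifications, LOOCV), prediction and
persistence.

Shared-location training entries (PO_MITO, ...) are excluded from
training by default — the classifier is defined over the three unique
classes — but any point can still be scored at prediction time.
Ties in the predicted class are broken by the fixed order
PO > MITO > ER so output is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .io import DatasetEntry, SINGLE_LOCATIONS

__all__ = [
    "CLASS_ORDER",
    "LabeledExample",
    "PredictionResult",
    "TargetingModel",
    "TargetingResults",
    "loocv_misclassifications",
    "load_model",
    "save_model",
]

logger = logging.getLogger(__name__)

#: Fixed class order; also the argmax tie-break preference.
CLASS_ORDER = ("PO", "MITO", "ER")

FEATURE_NAMES = ("tail_charge", "tmd_gravy")

MODEL_FORMAT = "tapredict-model"
MODEL_FORMAT_VERSION = 1

#: Margin below which the top two class probabilities are flagged.
AMBIGUITY_MARGIN = 0.1


@dataclass(frozen=True)
class LabeledExample:
    """One training point: (tail charge, TMD GRAVY) plus class label."""

    id: str
    tail_charge: float
    tmd_gravy: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in CLASS_ORDER:
            raise ValueError(f"label {self.label!r} not in {CLASS_ORDER}")
        if not np.isfinite([self.tail_charge, self.tmd_gravy]).all():
            raise ValueError(f"non-finite features for {self.id!r}")


@dataclass(frozen=True)
class PredictionResult:
    """Calibrated class probabilities for one protein."""

    id: str
    p_PO: float
    p_MITO: float
    p_ER: float
    predicted: str
    margin_note: str | None = None

    @property
    def probabilities(self) -> dict[str, float]:
        return {"PO": self.p_PO, "MITO": self.p_MITO, "ER": self.p_ER}


def _as_xy(
    X, y, ids
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must be (n, 2): columns tail_charge, tmd_gravy")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    y = np.asarray(y, dtype=object)
    if y.shape[0] != X.shape[0]:
        raise ValueError("X and y lengths differ")
    unknown = sorted(set(y) - set(CLASS_ORDER))
    if unknown:
        raise ValueError(f"labels outside {CLASS_ORDER}: {unknown}")
    if ids is None:
        ids = [f"x{i + 1}" for i in range(X.shape[0])]
    return X, y, list(map(str, ids))


def _fingerprint(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(np.round(X, 9)).tobytes())
    h.update("|".join(map(str, y)).encode())
    return h.hexdigest()


class TargetingModel:
    """Unfitted targeting classifier: data plus hyperparameters.

    Parameters
    ----------
    X : (n, 2) array
        Columns ``tail_charge``, ``tmd_gravy``.
    y : length-n labels out of PO / MITO / ER.
    ids : optional record identifiers.
    C, gamma : SVM cost and RBF width (defaults: libsvm defaults for
        two features).
    standardize : fit per-feature standardization on the training set.
    seed : seed for the internal cross-validation used by Platt
        calibration; fixed so runs are exactly reproducible.
    """

    def __init__(
        self,
        X,
        y,
        ids: Sequence[str] | None = None,
        *,
        C: float = 1.0,
        gamma: float = 0.5,
        standardize: bool = True,
        seed: int = 0,
    ):
        self.X, self.y, self.ids = _as_xy(X, y, ids)
        classes, counts = np.unique(self.y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need at least 2 classes to train")
        starved = [f"{c} (n={n})" for c, n in zip(classes, counts) if n < 2]
        if starved:
            raise ValueError("class(es) with < 2 examples: " + ", ".join(starved))
        self.C = float(C)
        self.gamma = float(gamma)
        self.standardize = bool(standardize)
        self.seed = int(seed)

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        *,
        label_col: str = "label",
        id_col: str = "id",
        **kwargs,
    ) -> "TargetingModel":
        """Build from a DataFrame with tail_charge/tmd_gravy/label columns."""
        ids = df[id_col] if id_col in df.columns else None
        return cls(
            df[list(FEATURE_NAMES)].to_numpy(dtype=float),
            df[label_col].to_numpy(),
            ids=None if ids is None else list(ids),
            **kwargs,
        )

    @classmethod
    def from_entries(
        cls,
        entries: Sequence[DatasetEntry],
        *,
        include_shared: bool = False,
        pH: float = 7.0,
        **kwargs,
    ) -> "TargetingModel":
        """Build from labeled dataset entries, computing features.

        Shared-location entries are dropped by default; with
        ``include_shared=True`` each is duplicated into its component
        classes instead.  Entries with no TMD (none detected, no
        coordinates) are skipped with a log message.
        """
        from .pipeline import dataset_features

        table = dataset_features(entries)
        skipped = table.loc[table["status"] != "OK", "id"].tolist()
        if skipped:
            logger.warning("skipping %d entr(ies) without a TMD: %s",
                           len(skipped), ", ".join(skipped))
        ok = table[table["status"] == "OK"]
        feats, labels, ids = [], [], []
        for row in ok.itertuples(index=False):
            x = (row.tail_charge, row.tmd_gravy)
            if row.location in SINGLE_LOCATIONS:
                feats.append(x); labels.append(row.location); ids.append(row.id)
            elif include_shared:
                for part in row.location.split("_"):
                    feats.append(x); labels.append(part)
                    ids.append(f"{row.id}:{part}")
        return cls(np.array(feats, dtype=float), labels, ids=ids, **kwargs)

    # -- fitting ---------------------------------------------------------

    def fit(self) -> "TargetingResults":
        """Fit the standardizer and the probabilistic one-vs-one SVM."""
        if self.standardize:
            mean = self.X.mean(axis=0)
            sd = self.X.std(axis=0)
        else:
            mean = np.zeros(2)
            sd = np.ones(2)
        if np.any(sd <= 0):
            bad = [FEATURE_NAMES[i] for i in np.flatnonzero(sd <= 0)]
            raise ValueError(f"zero-variance feature(s): {', '.join(bad)}")
        Z = (self.X - mean) / sd
        svc = SVC(
            C=self.C,
            kernel="rbf",
            gamma=self.gamma,
            probability=True,
            random_state=self.seed,
        )
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=FutureWarning)
            svc.fit(Z, self.y.astype(str))
        return TargetingResults(
            svc=svc,
            mean=mean,
            sd=sd,
            standardize=self.standardize,
            C=self.C,
            gamma=self.gamma,
            seed=self.seed,
            n_obs=len(self.y),
            fingerprint=_fingerprint(self.X, self.y),
            train_ids=self.ids,
            train_X=self.X,
            train_y=self.y,
        )

    def loocv_misclassifications(self) -> int:
        """Leave-one-out CV error count with fresh standardization per fold.

        A class left with fewer than two points in a training fold
        cannot be trained on and is dropped from that fold (logged); the
        held-out point counts as misclassified when its own label was
        dropped.  A fold with fewer than two trainable classes left is
        an error.
        """
        n = len(self.y)
        wrong = 0
        for i in range(n):
            keep = np.ones(n, dtype=bool)
            keep[i] = False
            rest_y = self.y[keep]
            classes, counts = np.unique(rest_y, return_counts=True)
            trainable = {c for c, k in zip(classes, counts) if k >= 2}
            if len(trainable) < 2:
                raise ValueError(
                    f"LOOCV fold {i}: fewer than 2 classes with >= 2 examples remain"
                )
            dropped = set(self.y) - trainable
            if dropped:
                logger.warning(
                    "LOOCV fold %d: class(es) %s starved below 2 examples; "
                    "dropped from the training fold",
                    i, ", ".join(sorted(dropped)),
                )
            sel = keep & np.isin(self.y, sorted(trainable))
            fold = TargetingModel(
                self.X[sel], self.y[sel],
                C=self.C, gamma=self.gamma,
                standardize=self.standardize, seed=self.seed,
            ).fit()
            if self.y[i] not in trainable:
                wrong += 1  # its label cannot be predicted by this fold
                continue
            pred = fold.predict(self.X[i : i + 1])[0].predicted
            if pred != self.y[i]:
                wrong += 1
        return wrong


class TargetingResults:
    """Fitted targeting classifier: parameters, predictions, diagnostics."""

    def __init__(
        self,
        *,
        svc: SVC,
        mean: np.ndarray,
        sd: np.ndarray,
        standardize: bool,
        C: float,
        gamma: float,
        seed: int,
        n_obs: int,
        fingerprint: str,
        train_ids: list[str] | None = None,
        train_X: np.ndarray | None = None,
        train_y: np.ndarray | None = None,
    ):
        self._svc = svc
        self.mean = np.asarray(mean, dtype=float)
        self.sd = np.asarray(sd, dtype=float)
        self.standardize = standardize
        self.C = C
        self.gamma = gamma
        self.seed = seed
        self.n_obs = n_obs
        self.fingerprint = fingerprint
        self.train_ids = train_ids
        self.train_X = train_X
        self.train_y = train_y

    # -- prediction ------------------------------------------------------

    def predict_proba(self, X) -> np.ndarray:
        """(n, 3) class probabilities in the fixed order PO, MITO, ER.

        Rows sum to 1 (renormalized against pairwise-coupling rounding);
        classes absent from the training fold get probability 0.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != 2 or not np.all(np.isfinite(X)):
            raise ValueError("X must be finite with 2 columns")
        Z = (X - self.mean) / self.sd
        with warnings.catch_warnings():
            warnings.filterwarnings("ignore", category=FutureWarning)
            raw = self._svc.predict_proba(Z)
        out = np.zeros((X.shape[0], len(CLASS_ORDER)))
        for j, cls in enumerate(self._svc.classes_):
            out[:, CLASS_ORDER.index(cls)] = raw[:, j]
        return out / out.sum(axis=1, keepdims=True)

    def predict(self, X, ids: Sequence[str] | None = None) -> list[PredictionResult]:
        """Per-record :class:`PredictionResult` with ambiguity notes."""
        proba = self.predict_proba(X)
        if ids is None:
            ids = [f"x{i + 1}" for i in range(proba.shape[0])]
        results = []
        for rec_id, p in zip(ids, proba):
            best = int(np.argmax(p))  # first max wins: PO > MITO > ER
            order = np.sort(p)[::-1]
            note = None
            if order[0] - order[1] < AMBIGUITY_MARGIN:
                runner = int(np.argsort(p, kind="stable")[::-1][1])
                note = (
                    f"ambiguous: {CLASS_ORDER[best]} vs {CLASS_ORDER[runner]} "
                    f"(dp={order[0] - order[1]:.3f})"
                )
            results.append(
                PredictionResult(
                    id=str(rec_id),
                    p_PO=float(p[0]),
                    p_MITO=float(p[1]),
                    p_ER=float(p[2]),
                    predicted=CLASS_ORDER[best],
                    margin_note=note,
                )
            )
        return results

    # -- diagnostics -----------------------------------------------------

    def in_sample_misclassifications(self, X=None, y=None) -> int:
        """Count of labeled points whose argmax class differs from the label."""
        if X is None:
            X, y = self.train_X, self.train_y
            if X is None:
                raise ValueError("no training data attached; pass X and y")
        y = np.asarray(y, dtype=object)
        preds = [r.predicted for r in self.predict(X)]
        return int(sum(p != t for p, t in zip(preds, y)))

    def evaluate(self, X, y, ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Per-record report (id, label, probabilities, predicted, correct).

        Warns when the evaluated data differ from the training set the
        model fingerprint was taken on.
        """
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=object)
        if _fingerprint(X, y) != self.fingerprint:
            warnings.warn(
                "evaluating on data that differ from the training set "
                "(fingerprint mismatch)",
                UserWarning,
                stacklevel=2,
            )
        rows = []
        for res, label in zip(self.predict(X, ids=ids), y):
            rows.append(
                {
                    "id": res.id,
                    "label": label,
                    "p_PO": res.p_PO,
                    "p_MITO": res.p_MITO,
                    "p_ER": res.p_ER,
                    "predicted": res.predicted,
                    "correct": res.predicted == label,
                }
            )
        return pd.DataFrame(rows)

    def probability_grid(
        self,
        charge_range: tuple[float, float],
        gravy_range: tuple[float, float],
        step: float = 0.1,
    ) -> pd.DataFrame:
        """Class probabilities on a rectangular (charge, GRAVY) lattice.

        Plot-ready long-format table; the decision contours of the
        published probability plot are level sets of these columns.
        """
        if step <= 0:
            raise ValueError("step must be > 0")
        charges = np.arange(charge_range[0], charge_range[1] + step / 2, step)
        gravies = np.arange(gravy_range[0], gravy_range[1] + step / 2, step)
        if charges.size == 0 or gravies.size == 0:
            raise ValueError("empty grid range")
        cc, gg = np.meshgrid(charges, gravies, indexing="ij")
        pts = np.column_stack([cc.ravel(), gg.ravel()])
        proba = self.predict_proba(pts)
        argmax = [CLASS_ORDER[i] for i in proba.argmax(axis=1)]
        return pd.DataFrame(
            {
                "tail_charge": pts[:, 0],
                "tmd_gravy": pts[:, 1],
                "p_PO": proba[:, 0],
                "p_MITO": proba[:, 1],
                "p_ER": proba[:, 2],
                "argmax": argmax,
            }
        )

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Tail-anchored protein targeting SVM",
            "=" * 40,
            f"observations:      {self.n_obs}",
            f"features:          {', '.join(FEATURE_NAMES)}",
            f"kernel:            RBF (gamma={self.gamma:g}), C={self.C:g}",
            f"standardized:      {self.standardize}"
            + (
                f"  (mean=[{self.mean[0]:.3f}, {self.mean[1]:.3f}],"
                f" sd=[{self.sd[0]:.3f}, {self.sd[1]:.3f}])"
                if self.standardize
                else ""
            ),
            f"calibration seed:  {self.seed}",
            f"classes:           {', '.join(self._svc.classes_)}",
            "support vectors:   "
            + ", ".join(
                f"{c}={n}" for c, n in zip(self._svc.classes_, self._svc._n_support)
            ),
        ]
        if self.train_X is not None:
            wrong = self.in_sample_misclassifications()
            pct = round(100.0 * wrong / self.n_obs)
            lines.append(
                f"in-sample error:   {wrong} of {self.n_obs} misclassified ({pct}%)"
            )
        lines.append(f"fingerprint:       {self.fingerprint[:16]}…")
        return "\n".join(lines)

    # -- persistence -----------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize to versioned JSON (lossless for prediction)."""
        svc = self._svc
        payload = {
            "format": MODEL_FORMAT,
            "format_version": MODEL_FORMAT_VERSION,
            "class_order": list(CLASS_ORDER),
            "feature_names": list(FEATURE_NAMES),
            "standardize": self.standardize,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "C": self.C,
            "gamma": self.gamma,
            "seed": self.seed,
            "n_obs": self.n_obs,
            "fingerprint": self.fingerprint,
            "svm": {
                "classes": svc.classes_.tolist(),
                "support": svc.support_.tolist(),
                "support_vectors": svc.support_vectors_.tolist(),
                "n_support": svc._n_support.tolist(),
                "dual_coef": svc._dual_coef_.tolist(),
                "intercept": svc._intercept_.tolist(),
                "probA": svc._probA.tolist(),
                "probB": svc._probB.tolist(),
                "n_iter": svc.n_iter_.tolist(),
                "class_weight": svc.class_weight_.tolist(),
                "shape_fit": list(svc.shape_fit_),
                "gamma_value": svc._gamma,
            },
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "TargetingResults":
        """Load a model saved by :meth:`save` (version-checked)."""
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as err:
            raise ValueError(f"{path}: corrupt model file ({err})") from err
        if payload.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path}: not a {MODEL_FORMAT} file")
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported model format version "
                f"{payload.get('format_version')!r} (expected {MODEL_FORMAT_VERSION})"
            )
        s = payload["svm"]
        svc = SVC(
            C=payload["C"],
            kernel="rbf",
            gamma=payload["gamma"],
            probability=True,
            random_state=payload["seed"],
        )
        svc.classes_ = np.asarray(s["classes"])
        svc.support_ = np.asarray(s["support"], dtype=np.int32)
        svc.support_vectors_ = np.asarray(s["support_vectors"], dtype=np.float64)
        svc._n_support = np.asarray(s["n_support"], dtype=np.int32)
        svc._dual_coef_ = np.asarray(s["dual_coef"], dtype=np.float64)
        svc.dual_coef_ = svc._dual_coef_
        svc._intercept_ = np.asarray(s["intercept"], dtype=np.float64)
        svc.intercept_ = svc._intercept_
        svc._probA = np.asarray(s["probA"], dtype=np.float64)
        svc._probB = np.asarray(s["probB"], dtype=np.float64)
        svc.n_iter_ = np.asarray(s["n_iter"], dtype=np.int32)
        svc.class_weight_ = np.asarray(s["class_weight"], dtype=np.float64)
        svc.shape_fit_ = tuple(s["shape_fit"])
        svc.fit_status_ = 0
        svc.n_features_in_ = len(payload["feature_names"])
        svc._sparse = False
        svc._gamma = s["gamma_value"]
        return cls(
            svc=svc,
            mean=np.asarray(payload["mean"], dtype=float),
            sd=np.asarray(payload["sd"], dtype=float),
            standardize=payload["standardize"],
            C=payload["C"],
            gamma=payload["gamma"],
            seed=payload["seed"],
            n_obs=payload["n_obs"],
            fingerprint=payload["fingerprint"],
        )


def loocv_misclassifications(
    X, y, *, C: float = 1.0, gamma: float = 0.5, standardize: bool = True, seed: int = 0
) -> int:
    """Functional wrapper around :meth:`TargetingModel.loocv_misclassifications`."""
    return TargetingModel(
        X, y, C=C, gamma=gamma, standardize=standardize, seed=seed
    ).loocv_misclassifications()


def save_model(results: TargetingResults, path: str | Path) -> None:
    results.save(path)


def load_model(path: str | Path) -> TargetingResults:
    return TargetingResults.load(path)
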