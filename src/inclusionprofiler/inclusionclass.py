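"""User-assisted random-forest classification of inclusion phenotypes.

A user (or, in tests, the simulator's ground truth) labels a small subset of
cells as inclusion-containing or not; a 100-tree random forest trained on
their normalized cytoprofiles scores the remaining population.  The review
protocol replicates the accuracy-assessment procedure of requesting a batch
of cells predicted as one bin, counting misclassifications against the
labeler, repeating three times, and growing the training set until accuracy
plateaus (~97%).  Per-well inclusion percentages are then enumerated.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cytoprofile import feature_columns

__all__ = [
    "TrainingSet",
    "ClassifierModel",
    "PlateSummary",
    "train",
    "review_protocol",
    "score_all",
    "summarize_wells",
    "corrected_prevalence",
    "INCLUSION",
    "NO_INCLUSION",
]

INCLUSION = "inclusion"
NO_INCLUSION = "no_inclusion"
BINS = (INCLUSION, NO_INCLUSION)

#: default decision threshold on the inclusion-class probability; ties
#: resolve to no_inclusion (conservative for a prevalence readout)
DECISION_THRESHOLD = 0.5


@dataclass
class TrainingSet:
    """Labeled normalized profiles for classifier training.

    ``profiles`` carries one row per cell with feature columns; ``labels``
    aligns with its index.  ``provenance`` records whether labels came from a
    human reviewer or a simulated oracle.
    """

    profiles: pd.DataFrame
    labels: pd.Series
    provenance: str = "user"

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, index=self.profiles.index)
        if self.profiles.index.duplicated().any():
            raise ValueError("duplicate cell ids in training set")
        if self.labels.nunique() < 2:
            raise ValueError("training set must contain >= 2 classes")

    @property
    def class_counts(self) -> pd.Series:
        return self.labels.value_counts()


@dataclass
class ClassifierModel:
    """Fitted random-forest ensemble with its fit-time feature schema."""

    forest: RandomForestClassifier
    feature_names: list[str]
    oob_accuracy: float | None = None
    threshold: float = DECISION_THRESHOLD

    def _check_schema(self, df: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in df.columns]
        if missing:
            raise ValueError(f"profiles missing fit-time features: {missing[:5]}")
        return df[self.feature_names].to_numpy(dtype=float)

    def predict(self, df: pd.DataFrame) -> tuple[pd.Series, pd.Series]:
        """Per-cell labels and inclusion-class probabilities.

        A cell is called ``inclusion`` only when its inclusion probability
        strictly exceeds the threshold.
        """
        X = self._check_schema(df)
        if len(X) == 0:
            empty = pd.Series(dtype=object, index=df.index)
            return empty, pd.Series(dtype=float, index=df.index)
        proba = self.forest.predict_proba(X)
        classes = list(self.forest.classes_)
        p_inc = proba[:, classes.index(INCLUSION)] if INCLUSION in classes else np.zeros(len(X))
        labels = np.where(p_inc > self.threshold, INCLUSION, NO_INCLUSION)
        return (pd.Series(labels, index=df.index),
                pd.Series(p_inc, index=df.index, name="p_inclusion"))

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump({"version": 1, "model": self}, fh)

    @classmethod
    def load(cls, path: str | Path) -> "ClassifierModel":
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
        return payload["model"]


def train(ts: TrainingSet, seed: int = 0, n_trees: int = 100) -> ClassifierModel:
    """Fit the random forest (100 trees, sqrt features per split, seeded).

    Deterministic given the seed; out-of-bag accuracy is reported on the
    model.  Requires >= 5 cells per class.
    """
    counts = ts.class_counts
    if (counts < 5).any():
        low = counts[counts < 5]
        raise ValueError(f"need >= 5 training cells per class; got {low.to_dict()}")
    feats = feature_columns(ts.profiles)
    X = ts.profiles[feats].to_numpy(dtype=float)
    y = ts.labels.to_numpy()
    forest = RandomForestClassifier(
        n_estimators=n_trees, max_features="sqrt", oob_score=True,
        random_state=seed, n_jobs=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # tiny sets may leave some samples in-bag only
        forest.fit(X, y)
    oob = float(forest.oob_score_) if hasattr(forest, "oob_score_") else None
    return ClassifierModel(forest=forest, feature_names=feats, oob_accuracy=oob)


def score_all(model: ClassifierModel, profiles: pd.DataFrame) -> pd.DataFrame:
    """Score every cell: predicted bin plus the retained inclusion probability."""
    labels, p_inc = model.predict(profiles)
    out = profiles.copy()
    out["predicted_label"] = labels
    out["p_inclusion"] = p_inc
    return out


def review_protocol(
    profiles: pd.DataFrame,
    oracle: "pd.Series | Callable[[pd.Index], pd.Series]",
    training_sizes: Sequence[int] = tuple(range(10, 151, 10)),
    batch: int = 100,
    repeats: int = 3,
    target_accuracy: float = 0.97,
    seed: int = 0,
    training_oracle: "pd.Series | None" = None,
) -> pd.DataFrame:
    """Accuracy-vs-training-size curve under the per-bin review procedure.

    For each training size n, a balanced set of n cells labeled by the oracle
    is drawn and a forest trained; then, ``repeats`` times per bin, ``batch``
    cells *predicted* as that bin are drawn from the remainder and scored
    against the oracle (a precision-like per-bin accuracy, matching the
    "request 100 cells of a bin and count mistakes" procedure).  Evaluation
    stops at the first size whose mean inclusion-bin accuracy reaches
    ``target_accuracy``.  ``training_oracle`` supplies the labels used for
    training when they should differ from the scoring oracle (default: the
    same oracle labels both).

    Returns a frame with columns (train_size, bin, mean_accuracy,
    sd_accuracy, n_scored) carrying ``plateau_size`` (or None) and
    ``converged`` in ``.attrs``.  If fewer than ``batch`` cells are predicted
    in a bin, all available are scored and the shortfall noted.
    """
    rng = np.random.default_rng(seed)
    truth = oracle(profiles.index) if callable(oracle) else pd.Series(oracle, index=profiles.index)
    train_truth = (pd.Series(training_oracle, index=profiles.index)
                   if training_oracle is not None else truth)
    rows = []
    plateau = None
    for size in training_sizes:
        per_class = max(size // 2, 5)
        train_idx: list = []
        for cls in BINS:
            pool = train_truth.index[train_truth == cls].to_numpy()
            if len(pool) < per_class:
                raise ValueError(f"oracle pool has only {len(pool)} {cls} cells; "
                                 f"cannot draw {per_class}")
            train_idx.extend(rng.choice(pool, per_class, replace=False))
        ts = TrainingSet(profiles.loc[train_idx], train_truth.loc[train_idx],
                         provenance="simulated oracle")
        model = train(ts, seed=int(rng.integers(2 ** 31)))
        rest = profiles.index.difference(pd.Index(train_idx))
        labels, _ = model.predict(profiles.loc[rest])
        for cls in BINS:
            predicted = labels.index[labels == cls].to_numpy()
            accs, n_scored = [], 0
            for _ in range(repeats):
                if len(predicted) == 0:
                    accs.append(0.0)
                    continue
                take = min(batch, len(predicted))
                drawn = rng.choice(predicted, take, replace=False)
                accs.append(float((truth.loc[drawn] == cls).mean()))
                n_scored = take
            rows.append({
                "train_size": 2 * per_class, "bin": cls,
                "mean_accuracy": float(np.mean(accs)),
                "sd_accuracy": float(np.std(accs)),
                "n_scored": n_scored,
            })
        inc_acc = rows[-2]["mean_accuracy"] if rows[-2]["bin"] == INCLUSION else rows[-1]["mean_accuracy"]
        if plateau is None and inc_acc >= target_accuracy:
            plateau = rows[-2]["train_size"]
            break
    curve = pd.DataFrame(rows)
    curve.attrs["plateau_size"] = plateau
    curve.attrs["converged"] = plateau is not None
    return curve


@dataclass
class PlateSummary:
    """Per-well inclusion counts and percentages, one row per well."""

    table: pd.DataFrame
    min_cells: int = 50

    def __post_init__(self) -> None:
        t = self.table
        assert ((t["pct_with_inclusions"] >= 0) & (t["pct_with_inclusions"] <= 100)).all()
        assert (t["n_with_inclusions"] <= t["n_cells_scored"]).all()

    @property
    def plate_pct(self) -> float:
        """Plate-level percentage over all scored cells."""
        n = self.table["n_cells_scored"].sum()
        k = self.table["n_with_inclusions"].sum()
        return 100.0 * k / n if n else 0.0


def summarize_wells(
    scored: pd.DataFrame,
    layout: pd.DataFrame | None = None,
    min_cells: int = 50,
) -> PlateSummary:
    """Enumerate per-well inclusion percentages from scored cells.

    Each cell's ``well`` must appear in the layout when one is given (orphan
    wells raise).  Wells with fewer than ``min_cells`` scored cells are
    flagged low-N but still reported.
    """
    if "predicted_label" not in scored.columns:
        raise ValueError("scored frame must carry 'predicted_label'")
    if layout is not None:
        known = set(layout["well"])
        orphans = sorted(set(scored["well"]) - known)
        if orphans:
            raise ValueError(f"cells in wells absent from layout: {orphans}")
    rows = []
    for well, g in scored.groupby("well", sort=True):
        n = len(g)
        k = int((g["predicted_label"] == INCLUSION).sum())
        row = {"well": well, "n_cells_scored": n, "n_with_inclusions": k,
               "pct_with_inclusions": 100.0 * k / n, "low_n": n < min_cells}
        if layout is not None:
            meta = layout.loc[layout["well"] == well].iloc[0]
            for col in ("construct", "dose_a", "dose_b", "replicate"):
                if col in meta.index:
                    row[col] = meta[col]
        rows.append(row)
    return PlateSummary(table=pd.DataFrame(rows), min_cells=min_cells)


def corrected_prevalence(observed: float, sensitivity: float, specificity: float) -> float:
    """Misclassification-corrected prevalence (Rogan-Gladen estimator).

    ``observed`` is the apparent inclusion fraction in [0, 1]; the corrected
    estimate (observed + specificity − 1) / (sensitivity + specificity − 1)
    is clipped to [0, 1].  Requires sensitivity + specificity > 1.
    """
    denom = sensitivity + specificity - 1.0
    if denom <= 0:
        raise ValueError("sensitivity + specificity must exceed 1")
    return float(np.clip((observed + specificity - 1.0) / denom, 0.0, 1.0))
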