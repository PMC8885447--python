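"""Checkerboard normalization and highest-single-agent (HSA) synergy scoring.

A checkerboard assay doses two compounds on a full factorial grid, including
the zero-dose margins, and reads out the percentage of transfected cells with
inclusions at each dose pair.  Responses are normalized to the no-drug control
well, converted to *effects* (percentage-point reduction in inclusion
formation), and compared against the HSA reference — the larger of the two
monotherapy effects at each dose pair.  The synergy score is the observed
excess over that reference; a mean score above 10 is called synergistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Checkerboard",
    "SynergyMatrix",
    "normalize_checkerboard",
    "hsa_synergy",
    "call_synergy",
    "SYNERGY_THRESHOLD",
]

#: score above which a dose pair is called synergistic (strict inequality)
SYNERGY_THRESHOLD = 10.0


@dataclass
class Checkerboard:
    """Dose-grid responses: rows index doses of drug A, columns drug B.

    ``replicates`` is a list of response matrices (% cells with inclusions,
    or % of control after normalization); ``response`` is their mean.
    Dose lists are ascending and start at 0, so ``response[0, 0]`` is the
    no-drug control.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    replicates: list[np.ndarray]
    normalized: bool = False

    def __post_init__(self) -> None:
        self.doses_a = np.asarray(self.doses_a, dtype=float)
        self.doses_b = np.asarray(self.doses_b, dtype=float)
        for name, d in (("doses_a", self.doses_a), ("doses_b", self.doses_b)):
            if d.ndim != 1 or d.size == 0:
                raise ValueError(f"{name} must be a nonempty 1-D sequence")
            if d[0] != 0:
                raise ValueError(f"{name} must start at dose 0 (control margin)")
            if np.any(np.diff(d) <= 0):
                raise ValueError(f"{name} must be strictly ascending")
        if not self.replicates:
            raise ValueError("at least one replicate response matrix is required")
        shape = (self.doses_a.size, self.doses_b.size)
        self.replicates = [np.asarray(r, dtype=float) for r in self.replicates]
        for r in self.replicates:
            if r.shape != shape:
                raise ValueError(f"replicate shape {r.shape} != dose grid {shape}")
            if np.any(r < 0):
                raise ValueError("responses must be nonnegative")

    @property
    def response(self) -> np.ndarray:
        """Mean response across replicates."""
        return np.mean(self.replicates, axis=0)

    @property
    def n_replicates(self) -> int:
        return len(self.replicates)

    @classmethod
    def from_csv(cls, paths: Sequence[str | Path]) -> "Checkerboard":
        """Read replicate grids from CSVs whose first row/column are the doses."""
        doses_a = doses_b = None
        reps = []
        for p in paths:
            df = pd.read_csv(p, index_col=0)
            da = df.index.to_numpy(dtype=float)
            db = df.columns.to_numpy(dtype=float)
            if doses_a is None:
                doses_a, doses_b = da, db
            elif not (np.array_equal(da, doses_a) and np.array_equal(db, doses_b)):
                raise ValueError(f"dose grid in {p} differs from first replicate")
            reps.append(df.to_numpy(dtype=float))
        return cls(doses_a=doses_a, doses_b=doses_b, replicates=reps)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(self.response, index=self.doses_a, columns=self.doses_b).to_csv(path)


@dataclass
class SynergyMatrix:
    """HSA synergy surface for one checkerboard.

    ``effect`` E(a,b) = 100 − normalized response, in percentage points of
    inclusion reduction; ``hsa_reference`` R(a,b) = max(E(a,0), E(0,b));
    ``score`` S(a,b) = E(a,b) − R(a,b), averaged across replicates, with
    ``score_sd`` the replicate standard deviation.
    """

    doses_a: np.ndarray
    doses_b: np.ndarray
    effect: np.ndarray
    hsa_reference: np.ndarray
    score: np.ndarray
    score_sd: np.ndarray
    n_replicates: int = 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.score, index=self.doses_a, columns=self.doses_b)


def normalize_checkerboard(raw: Checkerboard) -> Checkerboard:
    """Normalize each replicate grid as a percentage of its no-drug control well.

    The control cell of each normalized replicate is exactly 100; values above
    100 (worsening under drug) are retained.  Raises when any replicate's
    control is 0 (normalization undefined).
    """
    if raw.normalized:
        return raw
    norm = []
    for i, r in enumerate(raw.replicates):
        control = r[0, 0]
        if control <= 0:
            raise ValueError(f"replicate {i}: no-drug control is {control}; cannot normalize")
        norm.append(100.0 * r / control)
    return replace(raw, replicates=norm, normalized=True)


def _effect(normalized_grid: np.ndarray) -> np.ndarray:
    return 100.0 - normalized_grid


def hsa_synergy(norm: Checkerboard) -> SynergyMatrix:
    """Compute the HSA synergy matrix from a normalized checkerboard.

    Each replicate is scored separately (effect minus its own HSA reference)
    and the per-dose-pair mean across replicates is reported, mirroring the
    practice of reporting mean values from >= 3 separate experiments.
    """
    if not norm.normalized:
        norm = normalize_checkerboard(norm)
    scores = []
    for r in norm.replicates:
        e = _effect(r)
        ref = np.maximum.outer(e[:, 0], e[0, :])
        s = e - ref
        # a monotherapy margin IS its own highest-single-agent reference, so
        # its score is 0 by definition — including when the monotherapy
        # worsens the readout (negative effect, where max(E, 0) would
        # otherwise leak through)
        s[:, 0] = 0.0
        s[0, :] = 0.0
        scores.append(s)
    scores = np.asarray(scores)
    score = scores.mean(axis=0)
    assert np.all(score[:, 0] == 0) and np.all(score[0, :] == 0)
    e_mean = _effect(norm.response)
    ref_mean = np.maximum.outer(e_mean[:, 0], e_mean[0, :])
    return SynergyMatrix(
        doses_a=norm.doses_a,
        doses_b=norm.doses_b,
        effect=e_mean,
        hsa_reference=ref_mean,
        score=score,
        score_sd=scores.std(axis=0, ddof=0),
        n_replicates=norm.n_replicates,
    )


def call_synergy(sm: SynergyMatrix, threshold: float = SYNERGY_THRESHOLD) -> pd.DataFrame:
    """Tri-state call per dose pair: synergistic (S > threshold), antagonistic
    (S < −threshold), else neutral.  The inequality is strict: a score of
    exactly 10 is neutral."""
    calls = np.full(sm.score.shape, "neutral", dtype=object)
    calls[sm.score > threshold] = "synergistic"
    calls[sm.score < -threshold] = "antagonistic"
    return pd.DataFrame(calls, index=sm.doses_a, columns=sm.doses_b)


def plot_synergy_heatmap(sm: SynergyMatrix, path: str | Path | None = None,
                         units_a: str = "µM", units_b: str = "µM",
                         label_a: str = "drug A", label_b: str = "drug B"):
    """Render the synergy surface as an annotated heatmap with dose axes in µM."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.2 * len(sm.doses_b) + 2, 1.0 * len(sm.doses_a) + 2))
    vmax = max(10.0, np.abs(sm.score).max())
    im = ax.imshow(sm.score, cmap="RdBu_r", vmin=-vmax, vmax=vmax, origin="lower")
    ax.set_xticks(range(len(sm.doses_b)), [f"{d:g}" for d in sm.doses_b])
    ax.set_yticks(range(len(sm.doses_a)), [f"{d:g}" for d in sm.doses_a])
    ax.set_xlabel(f"{label_b} ({units_b})")
    ax.set_ylabel(f"{label_a} ({units_a})")
    for i in range(sm.score.shape[0]):
        for j in range(sm.score.shape[1]):
            ax.text(j, i, f"{sm.score[i, j]:.0f}", ha="center", va="center", fontsize=8)
    fig.colorbar(im, ax=ax, label="HSA synergy score")
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
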