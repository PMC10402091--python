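"""DCA evaluation of predicted binding sites against bound ligands.

DCA (distance from predicted site center to the closest ligand heavy atom)
declares a prediction successful when strictly below a threshold, 4 Å by
default. Two pooled metrics are built on it:

* **DCA recall** — fraction of ground-truth ligands recovered when only the
  top N (or N+2) ranked sites per system are considered, N being that
  system's ligand count. Sites are matched to ligands one-to-one, greedily
  by rank then by distance.
* **DCA precision** — fraction of considered predicted sites (top-M per
  system, or all) that succeed against *some* ligand; no exclusivity, so
  precision and recall stay independent.

Both pool counts over systems (micro averaging) and are reported as
percentages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .sites import BindingSite
from .types import InvalidInputError

__all__ = [
    "EvaluationCase",
    "MetricReport",
    "dca_success",
    "dca_recall",
    "dca_precision",
    "recall_threshold_sweep",
    "evaluate_cases",
]

DCA_THRESHOLD = 4.0  # Å, strict "below"


@dataclass
class EvaluationCase:
    """Ranked predictions and ground-truth ligand heavy-atom coordinates
    for one system."""

    sites: list[BindingSite]
    ligand_coords: list[np.ndarray]   # one (n_i, 3) array per ligand

    def __post_init__(self) -> None:
        ranks = [s.rank for s in self.sites]
        if ranks != list(range(1, len(ranks) + 1)):
            raise InvalidInputError("site ranks must be contiguous from 1")
        self.ligand_coords = [np.atleast_2d(np.asarray(c, float)) for c in self.ligand_coords]
        if any(c.size == 0 for c in self.ligand_coords):
            raise InvalidInputError("empty ligand in evaluation case")


def dca_success(center: np.ndarray, ligand: np.ndarray, threshold: float = DCA_THRESHOLD) -> bool:
    """True iff the minimum center-to-ligand-heavy-atom distance is
    strictly below the threshold."""
    ligand = np.atleast_2d(np.asarray(ligand, float))
    if ligand.size == 0:
        raise InvalidInputError("empty ligand")
    d = np.linalg.norm(ligand - np.asarray(center, float)[None, :], axis=1)
    return bool(d.min() < threshold)


def _min_dist(center: np.ndarray, ligand: np.ndarray) -> float:
    return float(np.linalg.norm(ligand - center[None, :], axis=1).min())


def dca_recall(
    cases: list[EvaluationCase],
    mode: str = "topN",
    threshold: float = DCA_THRESHOLD,
) -> float:
    """Pooled percentage of ligands recovered by the considered sites.

    ``mode`` is ``"topN"`` or ``"topN_plus_2"``. Per case the first N (or
    N+2) ranked sites are considered; each site can recover at most one
    ligand (greedy by rank, then nearest successful ligand).
    """
    if not cases:
        raise InvalidInputError("no evaluation cases")
    if mode not in ("topN", "topN_plus_2"):
        raise ValueError(f"unknown recall mode {mode!r}")
    recovered = 0
    total = 0
    for case in cases:
        n = len(case.ligand_coords)
        total += n
        k = n + 2 if mode == "topN_plus_2" else n
        considered = [s for s in case.sites if s.rank <= k]
        unmatched = list(range(n))
        for site in considered:  # already rank-ordered
            hits = [
                (li, _min_dist(site.center, case.ligand_coords[li]))
                for li in unmatched
            ]
            hits = [(li, d) for li, d in hits if d < threshold]
            if hits:
                li = min(hits, key=lambda h: h[1])[0]
                unmatched.remove(li)
                recovered += 1
    return 100.0 * recovered / total


def dca_precision(
    cases: list[EvaluationCase],
    mode: int | str = "all",
    threshold: float = DCA_THRESHOLD,
) -> float:
    """Pooled percentage of considered sites succeeding against some ligand.

    ``mode`` is an integer M (top-M sites per case) or ``"all"``. Returns
    NaN with a warning when no sites are considered at all.
    """
    if not cases:
        raise InvalidInputError("no evaluation cases")
    correct = 0
    considered_total = 0
    for case in cases:
        if mode == "all":
            considered = case.sites
        else:
            considered = [s for s in case.sites if s.rank <= int(mode)]
        considered_total += len(considered)
        for site in considered:
            if any(
                dca_success(site.center, lc, threshold) for lc in case.ligand_coords
            ):
                correct += 1
    if considered_total == 0:
        warnings.warn("no predicted sites to evaluate; precision undefined")
        return float("nan")
    return 100.0 * correct / considered_total


def recall_threshold_sweep(
    cases: list[EvaluationCase],
    thresholds,
    modes=("topN", "topN_plus_2"),
) -> pd.DataFrame:
    """DCA recall per success threshold per mode (long-format table)."""
    thresholds = list(thresholds)
    if any(b < a for a, b in zip(thresholds, thresholds[1:])):
        raise InvalidInputError("thresholds must be ascending")
    rows = [
        {"threshold": t, "mode": m, "recall": dca_recall(cases, m, t)}
        for t in thresholds
        for m in modes
    ]
    return pd.DataFrame(rows)


@dataclass
class MetricReport:
    """The standard five-column evaluation summary."""

    recall_topN: float
    recall_topN2: float
    precision_topM: dict[int, float] = field(default_factory=dict)
    precision_all: float = float("nan")
    n_ligands: int = 0
    n_sites: int = 0

    def to_frame(self) -> pd.DataFrame:
        row = {
            "recall_topN": self.recall_topN,
            "recall_topN_plus_2": self.recall_topN2,
        }
        for m, v in sorted(self.precision_topM.items()):
            row[f"precision_top{m}"] = v
        row["precision_all"] = self.precision_all
        row["n_ligands"] = self.n_ligands
        row["n_sites"] = self.n_sites
        return pd.DataFrame([row])


def evaluate_cases(
    cases: list[EvaluationCase],
    threshold: float = DCA_THRESHOLD,
    precision_caps=(3, 5),
) -> MetricReport:
    """Compute the full report: recall top-N / top-N+2, precision top-M / all."""
    return MetricReport(
        recall_topN=dca_recall(cases, "topN", threshold),
        recall_topN2=dca_recall(cases, "topN_plus_2", threshold),
        precision_topM={m: dca_precision(cases, m, threshold) for m in precision_caps},
        precision_all=dca_precision(cases, "all", threshold),
        n_ligands=sum(len(c.ligand_coords) for c in cases),
        n_sites=sum(len(c.sites) for c in cases),
    )
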