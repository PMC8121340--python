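"""Mean-absolute-error statistics between predicted and ground-truth traces.

The per-scan error is the mean over A-scan columns of the absolute row
distance between the two traces (in pixels at original B-scan resolution);
dataset-level figures are the mean and the population standard deviation of
the per-scan errors.  Reports follow the conventional layout: one (mean,
std) cell per group (AMD-like / control-like / all) and edge (ILM / RPE /
BM).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .boundary import BoundaryTrace

log = logging.getLogger(__name__)

EDGES = ("ILM", "RPE", "BM")
GROUP_ALL = "all"


def _rows(trace) -> np.ndarray:
    if isinstance(trace, BoundaryTrace):
        return trace.rows
    return np.asarray(trace, dtype=np.float64)


def mae_image(x, y) -> float:
    """Mean absolute row distance between two traces of one scan, in pixels.

    Columns missing (NaN) on either side are excluded pairwise; the excluded
    fraction is logged.  Raises if no column is shared.
    """
    xa, ya = _rows(x), _rows(y)
    if xa.shape != ya.shape:
        raise ValueError(f"trace lengths differ: {xa.shape} vs {ya.shape}")
    ok = ~(np.isnan(xa) | np.isnan(ya))
    n_excluded = int((~ok).sum())
    if not ok.any():
        raise ValueError("no common defined columns between the two traces")
    if n_excluded:
        log.info("mae_image: %d/%d columns excluded (missing on one side)",
                 n_excluded, len(xa))
    return float(np.abs(xa[ok] - ya[ok]).mean())


def _per_image_maes(X, Y) -> np.ndarray:
    if len(X) != len(Y) or len(X) == 0:
        raise ValueError(f"need equal, nonempty paired trace sets, got {len(X)} vs {len(Y)}")
    return np.array([mae_image(x, y) for x, y in zip(X, Y)])


def mae_mean(X, Y) -> float:
    """Mean over scans of the per-scan MAE."""
    return float(_per_image_maes(X, Y).mean())


def mae_std(X, Y, variance: bool = False) -> float:
    """Population standard deviation of the per-scan MAEs (divisor T).

    ``variance=True`` returns the mean squared deviation without the square
    root instead.
    """
    m = _per_image_maes(X, Y)
    v = float(((m - m.mean()) ** 2).mean())
    return v if variance else math.sqrt(v)


@dataclass
class EvaluationReport:
    """(group x edge) MAE table as a tidy DataFrame."""

    table: pd.DataFrame

    def cell(self, group: str, edge: str) -> tuple[float, float]:
        row = self.table[(self.table.group == group) & (self.table.edge == edge)]
        if row.empty:
            raise KeyError(f"no cell for group={group!r}, edge={edge!r}")
        return float(row.mae_mean.iloc[0]), float(row.mae_std.iloc[0])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.6f")

    def __str__(self) -> str:
        lines = [f"{'group':<14}{'edge':<6}{'MAE mean':>10}{'MAE std':>10}{'n':>5}"]
        for _, r in self.table.iterrows():
            lines.append(f"{r.group:<14}{r.edge:<6}{r.mae_mean:>10.3f}"
                         f"{r.mae_std:>10.3f}{int(r.n_scans):>5}")
        return "\n".join(lines)


def evaluate_dataset(pred: dict[str, dict[str, BoundaryTrace]],
                     gt: dict[str, dict[str, BoundaryTrace]],
                     groups: dict[str, str],
                     variance: bool = False) -> EvaluationReport:
    """Build the per-group, per-edge MAE report.

    ``pred`` and ``gt`` map scan_id -> {edge -> trace}; ``groups`` maps
    scan_id -> group label.  Scans missing any of the three edges on either
    side are excluded with a warning and reflected in the counts.
    """
    usable = []
    for sid in sorted(pred):
        if sid not in gt or sid not in groups:
            log.warning("evaluate_dataset: scan %s lacks ground truth or group; skipped", sid)
            continue
        if any(e not in pred[sid] or e not in gt[sid] for e in EDGES):
            log.warning("evaluate_dataset: scan %s missing an edge; skipped", sid)
            continue
        usable.append(sid)
    if not usable:
        raise ValueError("no scans usable for evaluation")

    group_names = sorted({groups[s] for s in usable})
    rows = []
    for gname in group_names + [GROUP_ALL]:
        sids = usable if gname == GROUP_ALL else [s for s in usable if groups[s] == gname]
        if not sids:
            continue
        for edge in EDGES:
            X = [pred[s][edge] for s in sids]
            Y = [gt[s][edge] for s in sids]
            rows.append({"group": gname, "edge": edge,
                         "mae_mean": mae_mean(X, Y),
                         "mae_std": mae_std(X, Y, variance=variance),
                         "n_scans": len(sids)})
    return EvaluationReport(table=pd.DataFrame(rows))
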