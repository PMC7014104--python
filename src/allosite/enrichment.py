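"""Docking-score analysis: distributions, ROC AUC enrichment, pose RMSD.

Docking itself (and decoy generation) happens upstream; this module consumes
tabulated results.  Scores are in kcal/mol with the Glide-style convention
that more negative is better.  The key readouts are:

* :func:`score_shift` — mean score improvement of a confirmed-active series
  over the rest of the library (positive = actives score better);
* :func:`roc_auc` — probability that a random active outranks a random
  decoy, computed by the rank-sum (Mann–Whitney) statistic with half-credit
  for ties;
* :func:`pose_rmsd` — in-place heavy-atom RMSD between a redocked pose and
  the native crystallographic pose (receptor frames already shared; no
  re-superposition), optionally minimized over user-supplied symmetry-
  equivalent atom mappings;
* :func:`distribution_summary` — per-class score summaries and the
  histogram-overlap coefficient between classes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .errors import EmptyInputError, RosterMismatchError

__all__ = [
    "DockingRecord",
    "EnrichmentReport",
    "read_scores",
    "score_shift",
    "roc_auc",
    "enrichment_report",
    "pose_rmsd",
    "distribution_summary",
    "overlap_coefficient",
]

CLASSES = ("active", "library", "decoy")


@dataclass(frozen=True)
class DockingRecord:
    """One docking result: ligand, target site, score and activity class."""

    ligand_id: str
    receptor: str
    site: str                      # "AF2" | "BF3"
    score: float                   # kcal/mol, lower = better
    label: str                     # "active" | "library" | "decoy"
    designed_for: str | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.score):
            raise ValueError(f"non-finite docking score for {self.ligand_id}")
        if self.label not in CLASSES:
            raise ValueError(f"class must be one of {CLASSES}, got {self.label!r}")


@dataclass
class EnrichmentReport:
    """Enrichment of an active series against decoys at one receptor/site."""

    auc: float
    n_active: int
    n_decoy: int
    mean_shift: float              # kcal/mol, positive = actives score better

    def __post_init__(self) -> None:
        if not (0.0 <= self.auc <= 1.0):
            raise ValueError(f"AUC {self.auc} outside [0, 1]")


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read a docking-score table (CSV or TSV).

    Required columns: ligand_id, receptor, site, score, class; optional:
    designed_for.  The ``class`` column must contain only
    active/library/decoy.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep)
    required = {"ligand_id", "receptor", "site", "score", "class"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path.name}: missing columns {sorted(missing)}")
    bad = set(df["class"]) - set(CLASSES)
    if bad:
        raise ValueError(f"{path.name}: unknown classes {sorted(bad)}")
    if not np.all(np.isfinite(df["score"].to_numpy(dtype=float))):
        raise ValueError(f"{path.name}: non-finite scores")
    return df


def score_shift(actives: Sequence[float], others: Sequence[float]) -> float:
    """Mean docking-score improvement of actives over another group (kcal/mol).

    ``mean(others) - mean(actives)``: with negative-better scores a positive
    shift means the actives score better on average.
    """
    actives = np.asarray(actives, dtype=float)
    others = np.asarray(others, dtype=float)
    if len(actives) == 0 or len(others) == 0:
        raise EmptyInputError("score_shift requires non-empty groups")
    return float(others.mean() - actives.mean())


def roc_auc(actives: Sequence[float], decoys: Sequence[float]) -> float:
    """P(random active ranks better than random decoy), ties counted half.

    Lower score = better rank.  Computed via the rank-sum statistic: with
    ascending ranks over the pooled scores, U = R_active − n_a(n_a+1)/2
    counts (decoy better than active) pairs plus half the ties, so
    AUC = 1 − U / (n_a · n_d).
    """
    a = np.asarray(actives, dtype=float)
    d = np.asarray(decoys, dtype=float)
    if len(a) == 0 or len(d) == 0:
        raise EmptyInputError("roc_auc requires non-empty groups")
    pooled = np.concatenate([a, d])
    ranks = rankdata(pooled)           # average ranks handle ties
    r_active = ranks[: len(a)].sum()
    u = r_active - len(a) * (len(a) + 1) / 2.0
    return float(1.0 - u / (len(a) * len(d)))


def enrichment_report(
    actives: Sequence[float],
    decoys: Sequence[float],
) -> EnrichmentReport:
    """AUC plus counts and mean score shift for one active-vs-decoy screen."""
    return EnrichmentReport(
        auc=roc_auc(actives, decoys),
        n_active=len(actives),
        n_decoy=len(decoys),
        mean_shift=score_shift(actives, decoys),
    )


def pose_rmsd(
    pose: Mapping[str, Sequence[float]] | pd.DataFrame,
    native: Mapping[str, Sequence[float]] | pd.DataFrame,
    symmetry_mappings: Sequence[Mapping[str, str]] | None = None,
) -> float:
    """In-place heavy-atom RMSD between a docked pose and the native pose.

    ``pose`` and ``native`` map atom names to 3D coordinates (dict or a
    DataFrame indexed by atom name with x/y/z columns).  The two rosters
    must match exactly; no re-superposition is applied because both poses
    live in the shared receptor frame.  If ``symmetry_mappings`` supplies
    automorphic atom-name remappings (e.g. for a flip-symmetric aromatic
    ring), the reported RMSD is the minimum over the identity and every
    supplied mapping.
    """
    def as_dict(obj) -> dict[str, np.ndarray]:
        if isinstance(obj, pd.DataFrame):
            return {str(i): row[["x", "y", "z"]].to_numpy(dtype=float)
                    for i, row in obj.iterrows()}
        return {str(k): np.asarray(v, dtype=float).reshape(3) for k, v in obj.items()}

    p = as_dict(pose)
    n = as_dict(native)
    if set(p) != set(n):
        raise RosterMismatchError(
            f"atom rosters differ: {sorted(set(p) ^ set(n))}"
        )
    if not p:
        raise EmptyInputError("empty pose")
    names = sorted(p)

    def rmsd_under(mapping: Mapping[str, str] | None) -> float:
        sq = 0.0
        for name in names:
            target = mapping.get(name, name) if mapping else name
            if target not in n:
                raise RosterMismatchError(f"symmetry mapping targets unknown atom {target!r}")
            sq += float(np.sum((p[name] - n[target]) ** 2))
        return float(np.sqrt(sq / len(names)))

    candidates = [rmsd_under(None)]
    for mapping in symmetry_mappings or ():
        candidates.append(rmsd_under(mapping))
    return min(candidates)


def overlap_coefficient(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    bin_width: float = 0.5,
) -> float:
    """Histogram-intersection overlap between two score distributions in [0, 1].

    Both samples are binned on a shared grid (width in kcal/mol) and the
    overlap is the summed minimum of the two normalized histograms: 1.0 for
    identical distributions, 0.0 for disjoint supports.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise EmptyInputError("overlap requires non-empty groups")
    lo = min(a.min(), b.min())
    hi = max(a.max(), b.max())
    edges = np.arange(lo, hi + 2 * bin_width, bin_width)
    ha, _ = np.histogram(a, bins=edges)
    hb, _ = np.histogram(b, bins=edges)
    pa = ha / ha.sum()
    pb = hb / hb.sum()
    return float(np.minimum(pa, pb).sum())


def distribution_summary(
    records: pd.DataFrame,
    bin_width: float = 0.5,
) -> pd.DataFrame:
    """Per-class score summaries (count, mean, median, IQR) plus pairwise overlap.

    Expects a DataFrame with ``score`` and ``class`` columns.  The returned
    summary has one row per class; pairwise histogram-overlap coefficients
    are attached in ``summary.attrs["overlap"]`` keyed by class pair.
    """
    if records.empty:
        raise EmptyInputError("no docking records")
    rows = []
    for label, grp in records.groupby("class"):
        s = grp["score"].to_numpy(dtype=float)
        q1, q3 = np.percentile(s, [25, 75])
        rows.append({
            "class": label, "count": len(s),
            "mean": float(s.mean()), "median": float(np.median(s)),
            "iqr": float(q3 - q1),
        })
    summary = pd.DataFrame(rows).set_index("class")
    overlap: dict[tuple[str, str], float] = {}
    labels = list(summary.index)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            overlap[(la, lb)] = overlap_coefficient(
                records.loc[records["class"] == la, "score"],
                records.loc[records["class"] == lb, "score"],
                bin_width,
            )
    summary.attrs["overlap"] = overlap
    return summary
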