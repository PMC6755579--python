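"""Virtual-screening pipeline and evaluation metrics.

Screening docks every compound in a library once against one receptor and
ranks the list by predicted binding affinity (lowest = best). Performance
against a labelled actives/decoys set is summarized by:

* success rate — percent of pose predictions with RMSD <= 2 A,
* AUC-ROC — probability that a random active outranks a random decoy
  (1.0 perfect, 0.5 random; ties count one half),
* enrichment factor EF_x% — the active fraction among the top x% of the
  ranked list divided by the active fraction overall.
"""

from __future__ import annotations

import logging
import math
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .engine import SearchBox, dock
from .ligand import SUCCESS_RMSD
from .optimizer import SwarmConfig
from .pdbqt import PDBQTError, parse_pdbqt_ligand
from .scoring import ScoringParams

__all__ = [
    "make_screening_table",
    "success_rate",
    "enrichment_factor",
    "auc_roc",
    "roc_curve_points",
    "screen",
    "screening_metrics",
]

logger = logging.getLogger(__name__)

_LABELS = ("active", "decoy")


def make_screening_table(rows) -> pd.DataFrame:
    """Normalize rows of (ligand_id, affinity, label) into a ranked table.

    Sorted by ascending affinity with ties broken by ligand_id; ids must
    be unique and labels in {active, decoy}.
    """
    if isinstance(rows, pd.DataFrame):
        df = rows[["ligand_id", "affinity", "label"]].copy()
    else:
        df = pd.DataFrame(rows, columns=["ligand_id", "affinity", "label"])
    if df["ligand_id"].duplicated().any():
        dupes = df.loc[df["ligand_id"].duplicated(), "ligand_id"].tolist()
        raise ValueError(f"duplicate ligand ids: {dupes}")
    bad = set(df["label"]) - set(_LABELS)
    if bad:
        raise ValueError(f"labels must be in {_LABELS}, got {sorted(bad)}")
    df["affinity"] = df["affinity"].astype(float)
    return df.sort_values(["affinity", "ligand_id"], kind="mergesort").reset_index(
        drop=True
    )


def success_rate(best_rmsds) -> float:
    """Percent of docking results with best-pose RMSD of 2 A or less."""
    r = np.asarray(list(best_rmsds), dtype=float)
    if r.size == 0:
        raise ValueError("no RMSD values")
    if np.any(r < 0):
        raise ValueError("RMSD cannot be negative")
    return 100.0 * float(np.mean(r <= SUCCESS_RMSD))


def enrichment_factor(table: pd.DataFrame, x_percent: float) -> float:
    """EF_x%: (actives in top floor(x% n) / total actives) / (x% n / n)."""
    if not 0.0 < x_percent <= 100.0:
        raise ValueError("x_percent must lie in (0, 100]")
    table = make_screening_table(table)
    n = len(table)
    if n == 0:
        raise ValueError("empty screening table")
    n_actives = int((table["label"] == "active").sum())
    if n_actives == 0:
        raise ValueError("screening table contains no actives")
    top = max(1, math.floor(x_percent / 100.0 * n))
    actives_top = int((table["label"].iloc[:top] == "active").sum())
    return (actives_top / n_actives) / (top / n)


def auc_roc(table: pd.DataFrame) -> float:
    """Rank-sum AUC: P(random active has lower affinity than random decoy),
    ties counted one half."""
    table = make_screening_table(table)
    is_active = (table["label"] == "active").to_numpy()
    n_act = int(is_active.sum())
    n_dec = int((~is_active).sum())
    if n_act == 0 or n_dec == 0:
        raise ValueError("AUC needs both actives and decoys")
    ranks = rankdata(table["affinity"].to_numpy())  # ascending, ties averaged
    u = float(ranks[is_active].sum()) - n_act * (n_act + 1) / 2.0
    return 1.0 - u / (n_act * n_dec)


def roc_curve_points(table: pd.DataFrame) -> pd.DataFrame:
    """(FPR, TPR) points over all thresholds of the ranked list."""
    table = make_screening_table(table)
    is_active = (table["label"] == "active").to_numpy()
    tpr = np.concatenate([[0.0], np.cumsum(is_active) / max(1, is_active.sum())])
    fpr = np.concatenate([[0.0], np.cumsum(~is_active) / max(1, (~is_active).sum())])
    return pd.DataFrame({"fpr": fpr, "tpr": tpr})


def screen(receptor_atoms, ligand_set, box: SearchBox,
           cfg: SwarmConfig | None = None, labels: dict | None = None,
           scoring: ScoringParams | None = None, n_runs: int = 1):
    """Dock a library once per compound and rank by best affinity.

    ``ligand_set`` maps ligand_id -> PDBQT path or text. Unparseable or
    failing ligands are recorded, not fatal. Returns ``(table, failures)``
    where failures is a list of (ligand_id, reason).
    """
    cfg = cfg or SwarmConfig(n_particles=16)
    labels = labels or {}
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(ligand_set))
    rows, failures = [], []
    for (ligand_id, source), sub in zip(sorted(ligand_set.items()), seeds):
        try:
            ligand = parse_pdbqt_ligand(
                Path(source) if isinstance(source, Path) else source
            )
            # one independent sub-seed per compound
            sub_cfg = replace(cfg, seed=int(sub.generate_state(1)[0] % (2**31)))
            poses = dock(receptor_atoms, ligand, box, cfg=sub_cfg,
                         n_runs=n_runs, scoring=scoring)
            rows.append(
                (ligand_id, poses[0].affinity, labels.get(ligand_id, "decoy"))
            )
        except (PDBQTError, RuntimeError, ValueError) as exc:
            logger.warning("screening failure for %s: %s", ligand_id, exc)
            failures.append((ligand_id, str(exc)))
    if not rows:
        raise RuntimeError("no ligand in the screening set could be docked")
    return make_screening_table(rows), failures


def screening_metrics(table: pd.DataFrame, ef_percents=(1.0, 20.0),
                      n_failed: int = 0) -> dict:
    """JSON-ready metric summary of a labelled screening table."""
    out = {"auc": auc_roc(table), "n_failed": int(n_failed)}
    for x in ef_percents:
        key = f"ef{x:g}".replace(".", "_")
        out[key] = enrichment_factor(table, x)
    return out
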