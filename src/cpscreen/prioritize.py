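"""Confidence-based compound prioritization and diversity reporting.

Compounds are ranked for explicit docking by the quality of information,
q = P1 - P0: the gap between the conformal confidence that a compound is a
virtual active and that it is a virtual inactive. For polypharmacology the
per-target qualities are summed, or — once docking results exist for every
target — compounds are sorted by the sum of their per-target docking ranks.
All rankings break ties by identifier so output order is a pure function of
the input tables.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .chem_io import FeatureMatrix

logger = logging.getLogger(__name__)

__all__ = ["rank_by_quality", "rank_multi_target", "rank_sum_combine",
           "diversity_report", "max_tanimoto_to_reference"]


def _as_pvalue_frame(table) -> pd.DataFrame:
    """Normalize a p-value table (DataFrame or id->(p1,p0) mapping)."""
    if isinstance(table, pd.DataFrame):
        df = table[["id", "p1", "p0"]].copy()
        df["id"] = df["id"].astype(str)
        return df
    rows = [(str(k), float(v[0]), float(v[1])) for k, v in table.items()]
    return pd.DataFrame(rows, columns=["id", "p1", "p0"])


def rank_by_quality(table, top_k: int | None = None) -> pd.DataFrame:
    """Sort compounds by q = p1 - p0, descending; ties by id ascending.

    ``table`` is a DataFrame with columns id, p1, p0 (or an id -> (p1, p0)
    mapping). Returns columns id, p1, p0, q, truncated to ``top_k`` if given.
    """
    df = _as_pvalue_frame(table)
    if df.empty:
        raise ValueError("empty p-value table")
    df["q"] = df["p1"] - df["p0"]
    df = df.sort_values(["q", "id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return df.head(top_k) if top_k is not None else df


def rank_multi_target(tables: Sequence, top_k: int | None = None) -> pd.DataFrame:
    """Rank compounds across targets by summed quality of information.

    q_sum = sum over targets of (p1 - p0). Only compounds present in every
    table are ranked; the rest are logged and excluded. With a single table
    this reduces to :func:`rank_by_quality`.
    """
    frames = [_as_pvalue_frame(t) for t in tables]
    if not frames:
        raise ValueError("no tables given")
    merged = frames[0].rename(columns={"p1": "p1_0", "p0": "p0_0"})
    for i, f in enumerate(frames[1:], start=1):
        merged = merged.merge(f.rename(columns={"p1": f"p1_{i}",
                                                "p0": f"p0_{i}"}),
                              on="id", how="inner")
    if merged.empty:
        raise ValueError("no compounds shared by all targets")
    n_dropped = max(len(f) for f in frames) - len(merged)
    if n_dropped > 0:
        logger.info("rank_multi_target: %d compounds missing from at least "
                    "one target were excluded", n_dropped)
    q_sum = np.zeros(len(merged))
    for i in range(len(frames)):
        q_sum += merged[f"p1_{i}"].to_numpy() - merged[f"p0_{i}"].to_numpy()
    merged["q_sum"] = q_sum
    merged = merged.sort_values(["q_sum", "id"], ascending=[False, True],
                                kind="mergesort").reset_index(drop=True)
    return merged.head(top_k) if top_k is not None else merged


def rank_sum_combine(rank_tables: Sequence[Mapping[str, int] | pd.DataFrame],
                     ) -> pd.DataFrame:
    """Combine per-target 1-based docking ranks by their sum (ascending).

    Compounds missing from any table are excluded and logged. Returns
    columns id, rank_sum plus per-target rank columns; ties by id.
    """
    frames = []
    for i, t in enumerate(rank_tables):
        if isinstance(t, pd.DataFrame):
            f = t[["id", "rank"]].copy()
            f["id"] = f["id"].astype(str)
        else:
            f = pd.DataFrame({"id": [str(k) for k in t],
                              "rank": [int(v) for v in t.values()]})
        frames.append(f.rename(columns={"rank": f"rank_{i}"}))
    if not frames:
        raise ValueError("no rank tables given")
    merged = frames[0]
    for f in frames[1:]:
        merged = merged.merge(f, on="id", how="inner")
    n_dropped = max(len(f) for f in frames) - len(merged)
    if n_dropped > 0:
        logger.info("rank_sum_combine: %d compounds missing from at least "
                    "one table were excluded", n_dropped)
    rank_cols = [c for c in merged.columns if c.startswith("rank_")]
    merged["rank_sum"] = merged[rank_cols].sum(axis=1)
    return merged.sort_values(["rank_sum", "id"], ascending=[True, True],
                              kind="mergesort").reset_index(drop=True)


def max_tanimoto_to_reference(selected: FeatureMatrix,
                              reference: FeatureMatrix,
                              block: int = 4096) -> np.ndarray:
    """Maximum Tanimoto similarity of each selected fingerprint to any
    reference fingerprint (blocked dense bit arithmetic)."""
    A = selected.bits.astype(np.float32)
    B = reference.bits.astype(np.float32)
    pa = A.sum(axis=1)
    pb = B.sum(axis=1)
    best = np.zeros(A.shape[0])
    for start in range(0, B.shape[0], block):
        Bb = B[start:start + block]
        inter = A @ Bb.T
        union = pa[:, None] + pb[start:start + block][None, :] - inter
        with np.errstate(invalid="ignore"):
            sim = np.where(union > 0, inter / union, 1.0)
        best = np.maximum(best, sim.max(axis=1))
    return best


def diversity_report(selected: FeatureMatrix, reference: FeatureMatrix,
                     thresholds: Sequence[float] = (0.2, 0.3, 0.4, 0.5,
                                                    0.6, 0.7, 0.8, 0.9),
                     selected_smiles: Sequence[str] | None = None,
                     ) -> pd.DataFrame:
    """Structural-similarity profile of a selection against a reference set.

    For each Tanimoto cutoff t: the fraction of selected compounds whose
    maximum similarity to the reference is >= t. When SMILES are supplied, a
    ``unique_scaffold_fraction`` column reports the fraction of selected
    compounds whose Bemis-Murcko framework (ring systems plus linkers, atom
    and bond types retained) occurs exactly once within the selection.
    """
    if len(selected) == 0 or len(reference) == 0:
        raise ValueError("selected and reference sets must be non-empty")
    if (selected.config is not None and reference.config is not None
            and selected.config != reference.config):
        raise ValueError("fingerprint configs differ between sets")
    best = max_tanimoto_to_reference(selected, reference)
    unique_frac = None
    if selected_smiles is not None:
        if len(selected_smiles) != len(selected):
            raise ValueError("selected_smiles must align with selected")
        scaffolds = []
        for smi in selected_smiles:
            mol = Chem.MolFromSmiles(smi)
            scaffolds.append(None if mol is None
                             else MurckoScaffold.MurckoScaffoldSmiles(mol=mol))
        counts = pd.Series([s for s in scaffolds if s is not None]).value_counts()
        n_unique = int(sum(1 for s in scaffolds
                           if s is not None and counts[s] == 1))
        unique_frac = n_unique / len(selected)
    rows = []
    for t in thresholds:
        rows.append({"threshold": float(t),
                     "fraction_similar": float(np.mean(best >= t)),
                     "unique_scaffold_fraction": unique_frac})
    return pd.DataFrame(rows)
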