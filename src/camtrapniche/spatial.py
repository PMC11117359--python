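"""Spatial niche overlap between two species via the Pianka index.

Each species' utilization of the study area is summarised by its per-site
RAI1 vector; the Pianka index is the normalised inner product of the two
utilization-proportion vectors, symmetric and scale-invariant, in [0, 1].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def pianka(u, v) -> float:
    """Pianka niche-overlap index of two aligned, non-negative vectors.

    O = Σ p_i q_i / sqrt(Σ p_i² · Σ q_i²), where p and q are the vectors
    rescaled to proportions. 0 means disjoint niches, 1 identical ones.
    """
    p = np.asarray(u, dtype=float)
    q = np.asarray(v, dtype=float)
    if p.shape != q.shape or p.ndim != 1 or len(p) < 2:
        raise ValueError("need two aligned 1-d vectors of equal length >= 2")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("utilization values must be non-negative")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("zero-sum utilization vector")
    p = p / p.sum()
    q = q / q.sum()
    return float(np.dot(p, q) / np.sqrt(np.dot(p, p) * np.dot(q, q)))


def seasonal_overlap_table(
    rai1_tables: dict[str, dict[str, pd.DataFrame]]
) -> pd.DataFrame:
    """One Pianka value per season from per-species RAI1 tables.

    Parameters
    ----------
    rai1_tables
        ``{season: {species: rai1_dataframe}}`` where each inner frame has
        columns ``camera_id`` and ``rai1``. Exactly two species per season;
        seasons missing a species or with mismatched site sets are omitted
        with a warning.

    Returns
    -------
    DataFrame with columns ``season`` and ``pianka`` (full precision; round
    at report time).
    """
    rows = []
    for season, by_species in rai1_tables.items():
        if len(by_species) != 2:
            logger.warning("season %s lacks both species — omitted", season)
            continue
        (sp_a, df_a), (sp_b, df_b) = sorted(by_species.items())
        a = df_a.set_index("camera_id")["rai1"]
        b = df_b.set_index("camera_id")["rai1"]
        if set(a.index) != set(b.index):
            raise ValueError(
                f"season {season}: site sets differ — only in {sp_a}: "
                f"{sorted(set(a.index) - set(b.index))}; only in {sp_b}: "
                f"{sorted(set(b.index) - set(a.index))}"
            )
        b = b.reindex(a.index)
        try:
            rows.append({"season": season, "pianka": pianka(a.to_numpy(), b.to_numpy())})
        except ValueError as exc:
            logger.warning("season %s: %s — omitted", season, exc)
    return pd.DataFrame(rows)
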