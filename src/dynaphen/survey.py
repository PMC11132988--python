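"""Affective state scores from the personal survey.

Pipeline: pivot responses to a (participant-session) x item matrix,
drop the free-text item and rows with any missing item, z-score each item
column across all rows (population s.d., so duplicating every row leaves
scores untouched), run PCA, keep the top two components, orient them by
their marker items (PC1 = valence, positive-emotion items load positively;
PC2 = arousal, affect-intensity items load positively), average the three
daily scores within each week, and linearly interpolate missing weeks per
participant *after* the PCA. State scores are finally normalized within
participant to span [-1, 1] across observed sessions.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .data import FREE_TEXT_ITEM, SurveyTable

__all__ = ["StateSeries", "compute_state_components", "normalize_states"]


@dataclasses.dataclass
class StateSeries:
    """Weekly valence/arousal scores per participant."""

    df: pd.DataFrame  # participant_id, week, valence, arousal, interpolated
    loadings: pd.DataFrame  # item_id, pc1, pc2
    explained_variance: tuple  # fraction per component


def _orient(scores, loadings, marker_cols, item_cols):
    """Flip a component so its marker items' loadings sum positive."""
    idx = [item_cols.index(i) for i in marker_cols if i in item_cols]
    if idx and loadings[idx].sum() < 0:
        return -scores, -loadings
    return scores, loadings


def compute_state_components(
    survey: SurveyTable,
    valence_items: list[int] | None = None,
    arousal_items: list[int] | None = None,
) -> StateSeries:
    """Z-score + PCA + weekly aggregation + per-participant interpolation.

    ``valence_items`` / ``arousal_items`` are the marker item ids used only
    to fix the sign convention of the two components (defaults match the
    synthetic survey's item map).
    """
    if valence_items is None:
        valence_items = list(range(1, 9))
    if arousal_items is None:
        arousal_items = list(range(17, 25))
    df = survey.df[survey.df["item_id"] != FREE_TEXT_ITEM]
    wide = df.pivot_table(
        index=["participant_id", "week", "day"],
        columns="item_id",
        values="response",
        aggfunc="first",
    )
    if wide.shape[1] < 2:
        raise ValueError("need at least 2 survey items")
    # rows with any missing item are dropped before PCA
    wide = wide.dropna(axis=0, how="any")
    if len(wide) < 3:
        raise ValueError("need at least 3 complete survey observations")
    X = wide.to_numpy(float)
    sd = X.std(axis=0, ddof=0)
    keep = sd > 1e-12
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} constant survey item(s)")
    item_cols = [int(c) for c, k in zip(wide.columns, keep) if k]
    X = X[:, keep]
    Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)

    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z)
    load = pca.components_.copy()  # (2, items)
    s1, l1 = _orient(scores[:, 0], load[0], valence_items, item_cols)
    s2, l2 = _orient(scores[:, 1], load[1], arousal_items, item_cols)

    daily = pd.DataFrame(
        dict(
            participant_id=wide.index.get_level_values(0),
            week=wide.index.get_level_values(1).astype(int),
            valence=s1,
            arousal=s2,
        )
    )
    weekly = (
        daily.groupby(["participant_id", "week"], as_index=False)[["valence", "arousal"]]
        .mean()
    )

    rows = []
    all_weeks = np.arange(1, int(df["week"].max()) + 1)
    for pid, g in weekly.groupby("participant_id"):
        g = g.sort_values("week")
        wk = g["week"].to_numpy()
        if len(wk) < 2:
            warnings.warn(f"participant {pid}: <2 observed sessions, no interpolation")
            for _, r in g.iterrows():
                rows.append((pid, int(r["week"]), r["valence"], r["arousal"], False))
            continue
        for w in all_weeks:
            interp = w not in set(wk)
            # np.interp holds the nearest observed value beyond the edges
            v = float(np.interp(w, wk, g["valence"].to_numpy()))
            a = float(np.interp(w, wk, g["arousal"].to_numpy()))
            rows.append((pid, int(w), v, a, interp))
    out = pd.DataFrame(
        rows, columns=["participant_id", "week", "valence", "arousal", "interpolated"]
    )
    loadings = pd.DataFrame(dict(item_id=item_cols, pc1=l1, pc2=l2))
    return StateSeries(
        df=out,
        loadings=loadings,
        explained_variance=tuple(float(v) for v in pca.explained_variance_ratio_),
    )


def normalize_states(series: StateSeries) -> StateSeries:
    """Affine map per participant and component: min -> -1, max -> +1.

    Constant series map to 0 everywhere.
    """
    df = series.df.copy()
    for col in ("valence", "arousal"):
        out = np.empty(len(df))
        for _, idx in df.groupby("participant_id").groups.items():
            x = df.loc[idx, col].to_numpy(float)
            lo, hi = np.min(x), np.max(x)
            if hi - lo < 1e-12:
                out[df.index.get_indexer(idx)] = 0.0
            else:
                out[df.index.get_indexer(idx)] = 2.0 * (x - lo) / (hi - lo) - 1.0
        df[col] = out
    return StateSeries(
        df=df, loadings=series.loadings, explained_variance=series.explained_variance
    )
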