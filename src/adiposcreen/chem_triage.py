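"""Nontarget-MS feature-table triage and MDC cross-referencing.

Features are retained for a sample when their abundance is strictly more
than ``fold_threshold`` times the blank abundance, or when they are absent
from every blank.  Retained features are tallied into a per-sample summary
(total features, features with MS2 spectra, features identified at or
above the score threshold, the identified share of MS2 features) and the
confident identifications are cross-referenced against a curated list of
metabolism-disrupting chemicals (MDCs) by compound identifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

FOLD_THRESHOLD = 10.0
SCORE_THRESHOLD = 40.0

FEATURE_META_COLUMNS = [
    "feature_id",
    "mz",
    "rt",
    "has_ms2",
    "best_id_name",
    "best_id_cid",
    "id_score",
]

TABLE1_COLUMNS = [
    "sample",
    "product",
    "n_features",
    "n_ms2",
    "n_id_ge_40",
    "pct_of_ms2",
    "mdc_hits",
]


class FeatureTableError(ValueError):
    pass


@dataclass(frozen=True)
class TriageSummary:
    sample: str
    n_features: int
    n_ms2: int
    n_id_ge_threshold: int
    pct_of_ms2: float | None
    mdc_hits: tuple[str, ...] = ()
    product: str = ""


def _blank_columns(table: pd.DataFrame, blank_cols: list[str] | None) -> list[str]:
    cols = blank_cols if blank_cols is not None else [
        c for c in table.columns if c.lower().startswith("blank")
    ]
    if not cols:
        raise FeatureTableError("feature table has no blank abundance columns")
    return cols


def filter_features(
    table: pd.DataFrame,
    sample_cols: list[str] | None = None,
    blank_cols: list[str] | None = None,
    fold_threshold: float = FOLD_THRESHOLD,
    blank_agg: str = "max",
) -> dict[str, pd.Series]:
    """Boolean retention mask per sample column.

    Retained iff ``abundance > fold_threshold * agg(blanks)`` (strict), or
    every blank is zero and the sample abundance is positive.  ``blank_agg``
    is ``"max"`` (default) or ``"mean"`` across blank columns.
    """
    blanks = _blank_columns(table, blank_cols)
    if sample_cols is None:
        sample_cols = [
            c for c in table.columns if c not in blanks and c not in FEATURE_META_COLUMNS
        ]
    if blank_agg == "max":
        blank_ref = table[blanks].max(axis=1)
    elif blank_agg == "mean":
        blank_ref = table[blanks].mean(axis=1)
    else:
        raise FeatureTableError(f"unknown blank_agg {blank_agg!r}")
    blank_all_zero = (table[blanks] == 0).all(axis=1)

    masks: dict[str, pd.Series] = {}
    for col in sample_cols:
        ab = table[col]
        masks[col] = (ab > fold_threshold * blank_ref) | (blank_all_zero & (ab > 0))
    return masks


def summarize_sample(
    retained: pd.DataFrame,
    sample: str,
    score_threshold: float = SCORE_THRESHOLD,
    *,
    product: str = "",
    mdc_hits: tuple[str, ...] = (),
) -> TriageSummary:
    """Tally one sample's retained features into a summary row.

    ``pct_of_ms2`` = 100 * identified / MS2-bearing, one decimal; None when
    no feature carries an MS2 spectrum.  The score threshold is inclusive.
    """
    n_features = int(len(retained))
    has_ms2 = retained["has_ms2"].astype(bool) if n_features else pd.Series(dtype=bool)
    n_ms2 = int(has_ms2.sum())
    if n_ms2:
        scores = pd.to_numeric(retained.loc[has_ms2, "id_score"], errors="coerce")
        n_id = int((scores >= score_threshold).sum())
        pct = round(100.0 * n_id / n_ms2, 1)
    else:
        n_id, pct = 0, None
    return TriageSummary(
        sample=sample,
        n_features=n_features,
        n_ms2=n_ms2,
        n_id_ge_threshold=n_id,
        pct_of_ms2=pct,
        mdc_hits=mdc_hits,
        product=product,
    )


def cross_reference_mdc(
    identified: pd.DataFrame,
    mdc_list: pd.DataFrame,
    score_threshold: float = SCORE_THRESHOLD,
) -> tuple[str, ...]:
    """Sorted unique MDC abbreviations among confidently identified features.

    Matching is by integer compound identifier (``best_id_cid`` against the
    MDC list's ``cid``); name matching is a warned fallback when a feature
    lacks a cid.
    """
    if identified.empty:
        return ()
    scores = pd.to_numeric(identified["id_score"], errors="coerce")
    confident = identified[scores >= score_threshold]
    if confident.empty:
        return ()
    by_cid = dict(zip(mdc_list["cid"].astype(int), mdc_list["abbreviation"]))
    by_name = dict(zip(mdc_list["name"].str.lower(), mdc_list["abbreviation"]))
    hits: set[str] = set()
    for _, row in confident.iterrows():
        cid = row.get("best_id_cid")
        if pd.notna(cid) and int(cid) in by_cid:
            hits.add(by_cid[int(cid)])
        elif pd.isna(cid) and pd.notna(row.get("best_id_name")):
            name = str(row["best_id_name"]).lower()
            if name in by_name:
                warnings.warn(
                    f"MDC matched by name fallback: {row['best_id_name']}", stacklevel=2
                )
                hits.add(by_name[name])
    return tuple(sorted(hits))


def triage(
    table: pd.DataFrame,
    mdc_list: pd.DataFrame,
    sample_cols: list[str] | None = None,
    blank_cols: list[str] | None = None,
    fold_threshold: float = FOLD_THRESHOLD,
    score_threshold: float = SCORE_THRESHOLD,
    blank_agg: str = "max",
    products: dict[str, str] | None = None,
) -> list[TriageSummary]:
    """Blank-filter, summarize and MDC-cross-reference every sample column."""
    masks = filter_features(table, sample_cols, blank_cols, fold_threshold, blank_agg)
    products = products or {}
    summaries = []
    for sample, mask in masks.items():
        retained = table[mask]
        hits = cross_reference_mdc(retained, mdc_list, score_threshold)
        summaries.append(
            summarize_sample(
                retained, sample, score_threshold,
                product=products.get(sample, ""), mdc_hits=hits,
            )
        )
    return summaries


def write_table1(summaries: list[TriageSummary], path: str | Path) -> Path:
    """Write the per-sample summary CSV in the canonical column order."""
    rows = [
        {
            "sample": s.sample,
            "product": s.product,
            "n_features": s.n_features,
            "n_ms2": s.n_ms2,
            "n_id_ge_40": s.n_id_ge_threshold,
            "pct_of_ms2": "" if s.pct_of_ms2 is None else f"{s.pct_of_ms2:.1f}",
            "mdc_hits": ";".join(s.mdc_hits),
        }
        for s in summaries
    ]
    frame = pd.DataFrame(rows, columns=TABLE1_COLUMNS)
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


# ---------------------------------------------------------------------------
# synthetic tables and packaged fixtures
# ---------------------------------------------------------------------------


def synthetic_feature_table(
    n_features: int,
    n_ms2: int,
    n_id: int,
    seed: int = 0,
    sample_col: str = "S1",
    *,
    mdc_cids: list[int] | None = None,
) -> pd.DataFrame:
    """Feature table whose blank filter retains exactly the requested counts.

    The first ``n_features`` rows pass the >10x blank rule for
    ``sample_col``; ``n_ms2`` of them carry MS2 spectra and ``n_id`` of
    those score >= 40.  A tail of blank-dominated decoy rows is appended so
    the filter actually has something to reject.  Optional ``mdc_cids``
    are planted (in order) on the highest-scoring identified rows.
    """
    if not (0 <= n_id <= n_ms2 <= n_features):
        raise ValueError("need 0 <= n_id <= n_ms2 <= n_features")
    rng = np.random.default_rng(seed)
    n_decoy = max(n_features // 5, 5)
    total = n_features + n_decoy

    mz = rng.uniform(80, 1200, total).round(4)
    rt = rng.uniform(0.5, 20.0, total).round(3)
    blank = np.zeros(total)
    sample = np.zeros(total)
    # retained block: blanks zero for half, low for the rest; sample strong
    blank[: n_features // 2] = 0.0
    blank[n_features // 2 : n_features] = rng.uniform(1, 50, n_features - n_features // 2)
    sample[:n_features] = blank[:n_features] * FOLD_THRESHOLD + rng.uniform(
        10, 1e4, n_features
    )
    # decoys: present in blanks, not enriched
    blank[n_features:] = rng.uniform(100, 1000, n_decoy)
    sample[n_features:] = blank[n_features:] * rng.uniform(0.2, FOLD_THRESHOLD, n_decoy)

    has_ms2 = np.zeros(total, dtype=bool)
    has_ms2[:n_ms2] = True
    score = np.full(total, np.nan)
    score[:n_id] = rng.uniform(SCORE_THRESHOLD, 100.0, n_id)
    score[n_id:n_ms2] = rng.uniform(0.0, SCORE_THRESHOLD - 1e-6, n_ms2 - n_id)
    name = np.where(has_ms2 & ~np.isnan(score), "compound", None)
    cid = np.where(has_ms2 & ~np.isnan(score), rng.integers(10_000_000, 99_999_999, total), -1)

    table = pd.DataFrame(
        {
            "feature_id": [f"F{i:05d}" for i in range(total)],
            "mz": mz,
            "rt": rt,
            sample_col: sample,
            "blank_1": blank,
            "has_ms2": has_ms2,
            "best_id_name": name,
            "best_id_cid": cid,
            "id_score": score,
        }
    )
    table.loc[table["best_id_cid"] == -1, "best_id_cid"] = pd.NA
    table["best_id_cid"] = table["best_id_cid"].astype("Int64")
    if mdc_cids:
        if len(mdc_cids) > n_id:
            raise ValueError("more MDC cids than identified features")
        idx = table.index[:n_id][: len(mdc_cids)]
        table.loc[idx, "best_id_cid"] = pd.array(mdc_cids, dtype="Int64")
    return table


def _load_packaged_csv(name: str) -> pd.DataFrame:
    with resources.files("adiposcreen").joinpath("data", name).open("r") as fh:
        return pd.read_csv(fh)


def load_mdc_list() -> pd.DataFrame:
    """Curated MDC list (name, cid, abbreviation); user-extensible via CSV."""
    return _load_packaged_csv("mdc_list.csv")


def load_reference_counts() -> pd.DataFrame:
    """Published per-sample feature counts used as arithmetic inputs.

    Rows with missing counts (samples that were not analyzed) are dropped.
    """
    frame = _load_packaged_csv("reference_counts.csv")
    return frame.dropna(subset=["n_features", "n_ms2", "n_id_ge_40"]).reset_index(drop=True)
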