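"""Labeling quantification from isotopomer search results.

Per molecule and sample: the ¹³C labeling ratio
(Σ heavy-isotopomer intensity / (Σ heavy + M+0 intensity)) and the
normalized isotopomer distribution (M+0…M+N fractions summing to 1).
Lipid summaries aggregate further by lipid class and by fatty-acid chain,
and a long-format time-course table supports condition × timepoint layouts.

No natural-abundance correction is applied anywhere: reported M+1/M+2
intensities include the ~1.1% per-carbon natural ¹³C background, and the
ratios are raw labeled fractions, not corrected enrichments.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .reference import ReferenceEntry

__all__ = [
    "LabelingSummary",
    "labeling_ratio",
    "isotopomer_distribution",
    "summarize",
    "summaries_to_frame",
    "aggregate_lipid_class",
    "aggregate_fatty_acid",
    "timecourse_table",
    "compare_conditions",
]


@dataclass
class LabelingSummary:
    """Per-(molecule, sample) labeling summary."""

    ref_id: str
    sample_id: str
    m0_intensity: float
    heavy_intensities: Dict[int, float]
    labeling_ratio: float
    distribution: Dict[int, float]
    flags: List[str] = field(default_factory=list)

    @property
    def heavy_total(self) -> float:
        return sum(self.heavy_intensities.values())


def _intensity_map(hits: pd.DataFrame) -> Dict[int, float]:
    if hits["ref_id"].nunique() > 1 or hits["sample_id"].nunique() > 1:
        raise ValueError("hits must belong to a single (ref_id, sample_id) group")
    return dict(zip(hits["n"].astype(int), hits["Intensity"].astype(float)))


def labeling_ratio(hits: pd.DataFrame) -> Tuple[float, List[str]]:
    """Labeled fraction of one molecule in one sample.

    Σ_{n≥1} I_n / (Σ_{n≥1} I_n + I_0). When heavy isotopomers were matched
    but M+0 was not (fully labeled pools can extinguish the unlabeled
    peak), returns 1.0 with an ``m0_missing`` flag rather than dropping
    the molecule. With no hits at all the ratio is undefined (raises;
    callers simply emit no record).
    """
    if not len(hits):
        raise ValueError("labeling_ratio is undefined without hits")
    by_n = _intensity_map(hits)
    m0 = by_n.get(0, 0.0)
    heavy = sum(v for n, v in by_n.items() if n >= 1)
    flags: List[str] = []
    if 0 not in by_n and heavy > 0:
        flags.append("m0_missing")
        return 1.0, flags
    denom = heavy + m0
    if denom == 0:
        flags.append("zero_intensity")
        return 0.0, flags
    return heavy / denom, flags


def isotopomer_distribution(hits: pd.DataFrame) -> Dict[int, float]:
    """Normalized isotopomer envelope: I_n / Σ I over all matched n (incl. 0)."""
    if not len(hits):
        raise ValueError("distribution is undefined without hits")
    by_n = _intensity_map(hits)
    total = sum(by_n.values())
    if total <= 0:
        raise ValueError("all matched intensities are zero; distribution undefined")
    return {n: v / total for n, v in sorted(by_n.items())}


def summarize(result: pd.DataFrame) -> List[LabelingSummary]:
    """Build per-(molecule, sample) summaries from a result table."""
    out: List[LabelingSummary] = []
    if not len(result):
        return out
    for (ref_id, sample_id), grp in result.groupby(["ref_id", "sample_id"], sort=True):
        by_n = _intensity_map(grp)
        ratio, flags = labeling_ratio(grp)
        try:
            dist = isotopomer_distribution(grp)
        except ValueError:
            dist = {}
        out.append(
            LabelingSummary(
                ref_id=ref_id,
                sample_id=sample_id,
                m0_intensity=by_n.get(0, 0.0),
                heavy_intensities={n: v for n, v in by_n.items() if n >= 1},
                labeling_ratio=ratio,
                distribution=dist,
                flags=flags,
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[LabelingSummary]) -> pd.DataFrame:
    rows = [
        (
            s.ref_id, s.sample_id, s.m0_intensity, s.heavy_total,
            s.labeling_ratio, ";".join(s.flags),
        )
        for s in summaries
    ]
    return pd.DataFrame(
        rows,
        columns=["ref_id", "sample_id", "m0_intensity", "heavy_total", "labeling_ratio", "flags"],
    )


def _ref_map(refs: Sequence[ReferenceEntry] | Mapping[str, ReferenceEntry]):
    return refs if isinstance(refs, Mapping) else {r.ref_id: r for r in refs}


def aggregate_lipid_class(
    summaries: Sequence[LabelingSummary],
    refs: Sequence[ReferenceEntry] | Mapping[str, ReferenceEntry],
) -> pd.DataFrame:
    """Mean labeling ratio per lipid class per sample (with member count)."""
    ref_map = _ref_map(refs)
    rows = []
    for s in summaries:
        ref = ref_map.get(s.ref_id)
        if ref is None or ref.mode != "lipid" or not ref.lipid_class:
            continue
        rows.append((ref.lipid_class, s.sample_id, s.labeling_ratio))
    if not rows:
        return pd.DataFrame(columns=["lipid_class", "sample_id", "mean_ratio", "n_lipids"])
    df = pd.DataFrame(rows, columns=["lipid_class", "sample_id", "ratio"])
    agg = (
        df.groupby(["lipid_class", "sample_id"], sort=True)["ratio"]
        .agg(mean_ratio="mean", n_lipids="count")
        .reset_index()
    )
    return agg


def aggregate_fatty_acid(
    summaries: Sequence[LabelingSummary],
    refs: Sequence[ReferenceEntry] | Mapping[str, ReferenceEntry],
) -> pd.DataFrame:
    """Mean labeling ratio per fatty-acid chain token per sample.

    A lipid contributes its summary once to each *distinct* chain it
    carries: PC(16:0/16:0) counts once toward 16:0. Lipids without parsed
    chains are skipped; the skip count is attached as ``DataFrame.attrs
    ["skipped_no_chains"]``.
    """
    ref_map = _ref_map(refs)
    rows = []
    skipped = 0
    for s in summaries:
        ref = ref_map.get(s.ref_id)
        if ref is None or ref.mode != "lipid":
            continue
        if not ref.fatty_acids:
            skipped += 1
            continue
        for chain in sorted(set(ref.fatty_acids)):
            rows.append((chain, s.sample_id, s.labeling_ratio))
    df = pd.DataFrame(rows, columns=["fatty_acid", "sample_id", "ratio"])
    agg = (
        df.groupby(["fatty_acid", "sample_id"], sort=True)["ratio"]
        .agg(mean_ratio="mean", n_lipids="count")
        .reset_index()
        if len(df)
        else pd.DataFrame(columns=["fatty_acid", "sample_id", "mean_ratio", "n_lipids"])
    )
    agg.attrs["skipped_no_chains"] = skipped
    return agg


def timecourse_table(
    summaries: Sequence[LabelingSummary],
    sample_map: Mapping[str, Tuple[str, float]],
) -> pd.DataFrame:
    """Long-format (ref, condition, timepoint, ratio) table.

    ``sample_map`` maps sample_id → (condition, timepoint), given either as
    a mapping or as an iterable of (sample_id, condition, timepoint) rows.
    Every sample appearing in the summaries must be mapped, and no sample
    may be mapped twice. Missing (ref, sample) summaries are simply absent
    rows, never zero-filled.
    """
    if not isinstance(sample_map, Mapping):
        rows_in = list(sample_map)
        ids = [r[0] for r in rows_in]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample mapping")
        sample_map = {sid: (cond, tp) for sid, cond, tp in rows_in}
    unmapped = sorted({s.sample_id for s in summaries} - set(sample_map))
    if unmapped:
        raise ValueError(f"unmapped sample(s): {unmapped}")
    rows = [
        (
            s.ref_id,
            sample_map[s.sample_id][0],
            sample_map[s.sample_id][1],
            s.sample_id,
            s.labeling_ratio,
        )
        for s in summaries
    ]
    df = pd.DataFrame(
        rows, columns=["ref_id", "condition", "timepoint", "sample_id", "labeling_ratio"]
    )
    return df.sort_values(
        ["ref_id", "condition", "timepoint", "sample_id"], kind="stable"
    ).reset_index(drop=True)


def compare_conditions(
    timecourse: pd.DataFrame,
    condition: str,
    vehicle: str,
    pseudo: float = 1e-6,
) -> pd.DataFrame:
    """Per-molecule log2 ratio and difference of labeling between a
    condition and the vehicle, matched on (ref_id, timepoint).

    A convenience for ranked fold-change views; no statistical test is
    attached. ``pseudo`` guards the log against zero ratios.
    """
    a = timecourse[timecourse["condition"] == condition]
    b = timecourse[timecourse["condition"] == vehicle]
    merged = a.merge(
        b, on=["ref_id", "timepoint"], suffixes=("_cond", "_veh"), how="inner"
    )
    merged["log2_ratio"] = np.log2(
        (merged["labeling_ratio_cond"] + pseudo) / (merged["labeling_ratio_veh"] + pseudo)
    )
    merged["difference"] = merged["labeling_ratio_cond"] - merged["labeling_ratio_veh"]
    return merged[
        ["ref_id", "timepoint", "labeling_ratio_cond", "labeling_ratio_veh",
         "log2_ratio", "difference"]
    ]
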