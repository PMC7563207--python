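"""Isotopomer search: match labeled-sample MS1 features to theoretical
isotopomer candidates with a joint m/z–RT score.

Each theoretical candidate (reference ion expanded to M+n) is compared
against features inside hard m/z (ppm) and RT pre-gates; among gated
features the best-scoring one is kept when its score clears the cutoff.
The score combines the m/z and RT deviations in one weighted Euclidean
distance,

    score = 1 − sqrt((Δm/z · β)² + ΔRT²),

with Δm/z in Th, ΔRT in seconds against the *reference* retention time
(isotopomers co-elute with the unlabeled molecule), and β (default 0.1)
balancing the two axes. score = 1 is a perfect match; the default cutoff
0.61 corresponds to a pure-RT deviation of 0.39 s.

The hard pre-gates matter: with β = 0.1 the m/z term is numerically tiny,
so a co-eluting ion ~0.07 Th away (e.g. the M+0 of a heavier co-eluting
lipid overlapping a high-n isotopomer) could otherwise outscore its
absence. A 10 ppm gate rejects such impostors outright.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Mapping, Sequence

import numpy as np
import pandas as pd

from .msdata import FEATURE_COLUMNS, Feature, features_to_frame
from .reference import IsotopomerCandidate, ReferenceEntry, build_candidates

logger = logging.getLogger(__name__)

__all__ = [
    "MatchParams",
    "score",
    "match_candidates",
    "assign_grade",
    "flux_result",
    "TABLE_COLUMNS",
    "RESULT_COLUMNS",
    "write_result_csv",
    "read_result_csv",
]

#: Exact output-table headers of the per-hit record.
TABLE_COLUMNS = [
    "mz1", "rt1", "Intensity", "mz2", "rt2", "Metabolite/Lipid",
    "fattyAcid", "lipidClass", "lipidForm", "Accession", "Theoretical_mz",
    "Adduct", "Charge", "Annotation", "Score", "dmz_ppm", "Grades",
]

#: Full result schema: sample bookkeeping around the record block.
RESULT_COLUMNS = ["sample_id"] + TABLE_COLUMNS + ["ref_id"]


@dataclass
class MatchParams:
    """Search parameters.

    beta          : m/z-vs-RT weight in the score (s·C/g); default 0.1.
    score_min     : score cutoff; default 0.61.
    mz_window_ppm : hard m/z pre-gate half-width (ppm); default 10.
    rt_window     : hard RT pre-gate half-width in rt units; default 30 s.
    rt_unit       : unit of ΔRT inside the score and of rt_window
                    ("seconds" default; "minutes" rescales the score's RT
                    axis so the 0.61 cutoff spans ±23.4 s).
    score_form    : "euclidean" (default) or "sum_of_squares".
    """

    beta: float = 0.1
    score_min: float = 0.61
    mz_window_ppm: float = 10.0
    rt_window: float = 30.0
    rt_unit: str = "seconds"
    score_form: str = "euclidean"

    def __post_init__(self) -> None:
        if not (0 < self.score_min <= 1):
            raise ValueError("score_min must lie in (0, 1]")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.mz_window_ppm <= 0 or self.rt_window <= 0:
            raise ValueError("gate windows must be positive")
        if self.rt_unit not in ("seconds", "minutes"):
            raise ValueError("rt_unit must be 'seconds' or 'minutes'")
        if self.score_form not in ("euclidean", "sum_of_squares"):
            raise ValueError("score_form must be 'euclidean' or 'sum_of_squares'")


def score(dmz, drt, beta: float = 0.1, score_form: str = "euclidean"):
    """Joint m/z–RT match score; 1 at a perfect match, lower with deviation.

    ``dmz`` is the m/z deviation in Th, ``drt`` the RT deviation in rt
    units; signs are ignored. May be negative for large deviations (such
    matches are always filtered by the cutoff). Accepts scalars or arrays.
    """
    dmz = np.abs(np.asarray(dmz, dtype=float))
    drt = np.abs(np.asarray(drt, dtype=float))
    d2 = (dmz * beta) ** 2 + drt**2
    s = 1.0 - (np.sqrt(d2) if score_form == "euclidean" else d2)
    return float(s) if s.ndim == 0 else s


GRADE_BINS = [(0.95, "A"), (0.85, "B"), (0.70, "C")]


def assign_grade(s: float, score_min: float = 0.61) -> str:
    """Letter grade for an accepted score: A ≥ 0.95, B ≥ 0.85, C ≥ 0.70, else D."""
    if s < score_min:
        raise ValueError(
            f"score {s} below cutoff {score_min}; sub-cutoff hits are never graded"
        )
    for edge, letter in GRADE_BINS:
        if s >= edge:
            return letter
    return "D"


def _as_feature_frame(features) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        missing = [c for c in ("mz", "rt_s", "intensity", "polarity") if c not in features.columns]
        if missing:
            raise ValueError(f"feature frame missing columns {missing}")
        return features
    return features_to_frame(features)


def match_candidates(
    candidates: Sequence[IsotopomerCandidate],
    refs: Sequence[ReferenceEntry] | Mapping[str, ReferenceEntry],
    features,
    params: MatchParams | None = None,
    sample_id: str = "",
) -> pd.DataFrame:
    """Search one sample's single-polarity feature list against candidates.

    For each candidate, features inside both hard gates (``mz_window_ppm``
    around the theoretical m/z; ``rt_window`` around the reference RT) are
    scored; the best-scoring feature is emitted as a hit iff its score
    clears ``score_min``. Score ties break toward higher intensity, then
    smaller |Δm/z|. At most one hit per candidate; one feature may serve
    several candidates (overlapping envelopes of different molecules are
    real). Multiply-used features are flagged in the ``feature_shared``
    column for audit.

    Returns a DataFrame in the result schema plus ``n`` / ``feature_shared``
    helper columns.
    """
    params = params or MatchParams()
    ref_map = refs if isinstance(refs, Mapping) else {r.ref_id: r for r in refs}
    fdf = _as_feature_frame(features)

    pols = set(fdf["polarity"].unique())
    cand_pols = {ref_map[c.ref_id].polarity for c in candidates}
    if len(pols) > 1 or len(cand_pols) > 1:
        raise ValueError("match_candidates requires a single polarity on both sides")
    if pols and cand_pols and pols != cand_pols:
        raise ValueError(f"feature polarity {pols} differs from candidate polarity {cand_pols}")

    order = np.argsort(fdf["mz"].to_numpy(), kind="stable")
    mz = fdf["mz"].to_numpy()[order]
    rt = fdf["rt_s"].to_numpy()[order]
    inten = fdf["intensity"].to_numpy()[order]

    rt_scale = 60.0 if params.rt_unit == "minutes" else 1.0
    rows = []
    feature_use: dict = {}
    for cand in candidates:
        ref = ref_map[cand.ref_id]
        th = cand.theoretical_mz
        tol = th * params.mz_window_ppm * 1e-6
        lo = np.searchsorted(mz, th - tol, side="left")
        hi = np.searchsorted(mz, th + tol, side="right")
        if hi <= lo:
            continue
        drt_u = (rt[lo:hi] - ref.rt) / rt_scale
        keep = np.abs(drt_u) <= params.rt_window
        if not keep.any():
            continue
        idx = np.flatnonzero(keep) + lo
        s = score(mz[idx] - th, drt_u[keep], params.beta, params.score_form)
        s = np.atleast_1d(s)
        # best score; ties -> higher intensity, then smaller |dmz|, then order
        adm = np.abs(mz[idx] - th)
        best = np.lexsort((adm, -inten[idx], -s))[0]
        if s[best] < params.score_min:
            continue
        j = idx[best]
        feature_use[j] = feature_use.get(j, 0) + 1
        rows.append(
            {
                "sample_id": sample_id or (fdf["sample_id"].iloc[0] if "sample_id" in fdf and len(fdf) else ""),
                "ref_id": ref.ref_id,
                "n": cand.n,
                "mz1": ref.mz,
                "rt1": ref.rt,
                "Intensity": inten[j],
                "mz2": mz[j],
                "rt2": rt[j],
                "Metabolite/Lipid": ref.name,
                "fattyAcid": "/".join(ref.fatty_acids) if ref.mode == "lipid" else "",
                "lipidClass": ref.lipid_class if ref.mode == "lipid" else "",
                "lipidForm": str(ref.formula) if (ref.mode == "lipid" and ref.formula) else "",
                "Accession": ref.accession,
                "Theoretical_mz": th,
                "Adduct": ref.adduct.name,
                "Charge": ref.adduct.z,
                "Annotation": cand.annotation,
                "Score": float(s[best]),
                "dmz_ppm": abs(mz[j] - th) / th * 1e6,
                "Grades": assign_grade(float(s[best]), params.score_min),
                "_feature_idx": int(j),
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS + ["n", "_feature_idx"])
    if len(df):
        df["feature_shared"] = df["_feature_idx"].map(lambda j: feature_use[j] > 1)
        shared = int(df["feature_shared"].sum())
        if shared:
            logger.info("%d hit(s) share a feature with another candidate", shared)
    else:
        df["feature_shared"] = pd.Series(dtype=bool)
    return df.drop(columns=["_feature_idx"])


def flux_result(
    refs: Sequence[ReferenceEntry],
    sample_inputs: Mapping[str, pd.DataFrame | Sequence[Feature]],
    params: MatchParams | None = None,
    n_max_metabolite: int = 10,
    n_max_lipid: int = 40,
    cap_by_formula: bool = True,
    out_csv: str | None = None,
) -> pd.DataFrame:
    """Run the full isotopomer search over every sample and polarity.

    Expands the pooled reference list into candidates, searches each
    sample's feature list polarity by polarity, and concatenates the hits
    into one result table (optionally written as CSV). Deterministic given
    identical inputs and parameters. Samples contributing zero features
    are retained in the run log with a warning but add no rows.
    """
    params = params or MatchParams()
    if not len(refs):
        raise ValueError("flux_result requires a non-empty reference pool")
    candidates = build_candidates(
        refs, n_max_metabolite=n_max_metabolite, n_max_lipid=n_max_lipid,
        cap_by_formula=cap_by_formula,
    )
    by_pol: dict = {}
    ref_map = {r.ref_id: r for r in refs}
    for cand in candidates:
        by_pol.setdefault(ref_map[cand.ref_id].polarity, []).append(cand)

    frames: List[pd.DataFrame] = []
    for sample_id in sorted(sample_inputs):
        fdf = _as_feature_frame(sample_inputs[sample_id])
        if not len(fdf):
            logger.warning("sample %s has zero features; no hits possible", sample_id)
            continue
        for polarity, cands in sorted(by_pol.items()):
            sub = fdf[fdf["polarity"] == polarity]
            if not len(sub):
                continue
            hits = match_candidates(cands, ref_map, sub, params, sample_id=sample_id)
            logger.info("sample %s [%s]: %d hits", sample_id, polarity, len(hits))
            if len(hits):
                frames.append(hits)
    cols = RESULT_COLUMNS + ["n", "feature_shared"]
    result = (
        pd.concat(frames, ignore_index=True)[cols]
        if frames
        else pd.DataFrame(columns=cols)
    )
    if out_csv is not None:
        write_result_csv(result, out_csv)
    return result


def write_result_csv(result: pd.DataFrame, path: str) -> None:
    """Write the result table with the documented headers (helper columns
    ``n``/``feature_shared`` kept after the record block for audit)."""
    cols = RESULT_COLUMNS + [c for c in ("n", "feature_shared") if c in result.columns]
    result[cols].to_csv(path, index=False)


def read_result_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in RESULT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing result columns {missing}")
    if "n" not in df.columns:
        df["n"] = df["Annotation"].str.extract(r"M\+(\d+)").astype(int)
    for col in ("mz1", "rt1", "Intensity", "mz2", "rt2", "Theoretical_mz", "Score", "dmz_ppm"):
        df[col] = pd.to_numeric(df[col])
    df["n"] = pd.to_numeric(df["n"]).astype(int)
    return df
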