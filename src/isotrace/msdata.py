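"""MS1 spectra input and feature (peak) detection.

Reads centroided mzML/mzXML, splits by ionization polarity and collapses
scan-by-scan centroids into chromatographic features (m/z, RT, intensity).
The trace builder joins centroids of consecutive scans within a ppm window
and breaks traces at retention-time gaps; peaks are local-maximum runs that
clear signal-to-noise and signal-to-baseline thresholds.

Pre-picked feature lists in CSV form (columns: sample_id, polarity, mz,
rt_s, intensity) bypass this module entirely and are a first-class input.
"""

from __future__ import annotations

import logging
import os
import warnings
from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Spectrum",
    "Feature",
    "PeakPickingParams",
    "read_ms1",
    "pick_features",
    "read_feature_table",
    "write_feature_table",
]

FEATURE_COLUMNS = ["sample_id", "polarity", "mz", "rt_s", "intensity"]

# Legacy picker knobs accepted for config provenance but without an
# analogue in this trace builder; their presence is logged and ignored.
IGNORED_PICKER_KEYS = frozenset(
    {"dmzgap", "drtdens", "drtfill", "drttotal", "recurs", "weight", "ended"}
)


@dataclass
class Spectrum:
    """One MS scan: RT in seconds, polarity, level and centroid arrays."""

    rt: float
    polarity: str
    ms_level: int
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.size and np.any(np.diff(self.mz) < 0):
            order = np.argsort(self.mz, kind="stable")
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if np.any(self.intensity < 0):
            raise ValueError("negative intensity in spectrum")


@dataclass(frozen=True)
class Feature:
    """A detected MS1 feature: intensity-weighted m/z, apex RT, intensity."""

    mz: float
    rt: float
    intensity: float
    polarity: str
    sample_id: str = ""


@dataclass
class PeakPickingParams:
    """Feature-detection parameters.

    mz_cluster_ppm : half-width of the trace m/z window (ppm).
    min_scans      : minimum points in a peak run.
    sn_min         : apex / trace-noise threshold (noise = median of
                     non-peak points, floored at 1 so S/N is defined on
                     clean simulated traces).
    sb_min         : apex / local-baseline threshold.
    min_intensity, max_intensity : apex intensity retention band.
    rt_gap_s       : RT gap that breaks a trace.
    rt_peak_window_s : maximum width of one peak run.
    intensity_measure : "apex" (default) or "area" reported per feature.
    """

    mz_cluster_ppm: float = 4.0
    min_scans: int = 3
    sn_min: float = 3.0
    sb_min: float = 2.0
    min_intensity: float = 1e4
    max_intensity: float = 1e7
    rt_gap_s: float = 300.0
    rt_peak_window_s: float = 20.0
    intensity_measure: str = "apex"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "mz_cluster_ppm", "min_scans", "sn_min", "sb_min",
            "min_intensity", "max_intensity", "rt_gap_s", "rt_peak_window_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_intensity >= self.max_intensity:
            raise ValueError("min_intensity must be < max_intensity")
        ignored = IGNORED_PICKER_KEYS.intersection(self.extra)
        if ignored:
            logger.info(
                "peak-picking parameters accepted for provenance but "
                "ignored: %s", ", ".join(sorted(ignored))
            )


# ---------------------------------------------------------------------------
# Reading


def _rt_seconds(scan_time, unit_minutes_default: bool = True) -> float:
    # pyteomics returns unitfloat with unit_info when available
    unit = getattr(scan_time, "unit_info", None)
    t = float(scan_time)
    if unit is not None and "minute" in str(unit):
        return t * 60.0
    if unit is not None and "second" in str(unit):
        return t
    return t * 60.0 if unit_minutes_default else t


_MZML_NS = "{http://psi.hupo.org/ms/mzml}"


def _decode_binary(elem) -> tuple[str | None, np.ndarray]:
    """Decode one <binaryDataArray>: returns (array kind, values)."""
    import base64
    import zlib as _zlib

    kind = None
    dtype = np.float64
    compressed = False
    for cv in elem.iter(_MZML_NS + "cvParam"):
        acc = cv.get("accession")
        if acc == "MS:1000514":
            kind = "mz"
        elif acc == "MS:1000515":
            kind = "intensity"
        elif acc == "MS:1000521":
            dtype = np.float32
        elif acc == "MS:1000574":
            compressed = True
    node = elem.find(_MZML_NS + "binary")
    text = (node.text or "") if node is not None else ""
    raw = base64.b64decode(text)
    if compressed:
        raw = _zlib.decompress(raw)
    return kind, np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_mzml_ms1(path: str):
    """Minimal mzML 1.1 MS1 reader (lxml iterparse, 32/64-bit, zlib or raw).

    Yields (rt_s, polarity, is_profile, mz, intensity) per MS1 spectrum.
    """
    from lxml import etree

    for _, spec in etree.iterparse(path, tag=_MZML_NS + "spectrum"):
        ms_level = None
        polarity = None
        profile = False
        rt = 0.0
        for cv in spec.findall(_MZML_NS + "cvParam"):
            acc = cv.get("accession")
            if acc == "MS:1000511":
                ms_level = int(cv.get("value"))
            elif acc == "MS:1000130":
                polarity = "positive"
            elif acc == "MS:1000129":
                polarity = "negative"
            elif acc == "MS:1000128":
                profile = True
        for cv in spec.iter(_MZML_NS + "cvParam"):
            if cv.get("accession") == "MS:1000016":
                t = float(cv.get("value"))
                unit = (cv.get("unitName") or "").lower()
                rt = t * 60.0 if "minute" in unit else t
                break
        if ms_level == 1:
            mz = inten = np.array([])
            for arr in spec.iter(_MZML_NS + "binaryDataArray"):
                kind, values = _decode_binary(arr)
                if kind == "mz":
                    mz = values
                elif kind == "intensity":
                    inten = values
            yield rt, polarity, profile, mz, inten
        spec.clear()


def _centroid_profile(mz: np.ndarray, inten: np.ndarray):
    """Naive local-maxima centroiding fallback for profile-mode scans."""
    if mz.size < 3:
        return mz, inten
    keep = (inten[1:-1] >= inten[:-2]) & (inten[1:-1] > inten[2:]) & (inten[1:-1] > 0)
    idx = np.flatnonzero(keep) + 1
    return mz[idx], inten[idx]


def read_ms1(path: str, polarity: str) -> List[Spectrum]:
    """Read MS1 scans of one polarity from an mzML or mzXML file.

    Returns spectra sorted by RT (seconds). Profile-mode scans trigger a
    warning and are centroided by naive local-maxima detection. A file
    whose scans carry no polarity metadata raises, instructing the caller
    to supply polarity-split input explicitly.
    """
    if polarity not in ("positive", "negative"):
        raise ValueError(f"polarity must be positive/negative, got {polarity!r}")
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    ext = os.path.splitext(path)[1].lower()
    spectra: List[Spectrum] = []
    profile_seen = False

    if ext == ".mzxml":
        from pyteomics import mzxml

        with mzxml.read(path) as reader:
            for scan in reader:
                if int(scan.get("msLevel", 0)) != 1:
                    continue
                pol = {"+": "positive", "-": "negative"}.get(scan.get("polarity"))
                if pol is None:
                    raise ValueError(
                        f"{path}: scan without polarity metadata; split the "
                        "file by polarity and pass the polarity flag explicitly"
                    )
                if pol != polarity:
                    continue
                rt = _rt_seconds(scan.get("retentionTime", 0.0))
                spectra.append(
                    Spectrum(rt, pol, 1, scan["m/z array"], scan["intensity array"])
                )
    else:
        for rt, pol, profile, mz, inten in _parse_mzml_ms1(path):
            if pol is None:
                raise ValueError(
                    f"{path}: scan without polarity metadata; split the "
                    "file by polarity and pass the polarity flag explicitly"
                )
            if pol != polarity:
                continue
            if profile:
                profile_seen = True
                mz, inten = _centroid_profile(mz, inten)
            spectra.append(Spectrum(rt, pol, 1, mz, inten))

    if profile_seen:
        warnings.warn(
            f"{path}: profile-mode spectra encountered; applied naive "
            "local-maxima centroiding", stacklevel=2
        )
    if not spectra:
        raise ValueError(f"{path}: no MS1 spectra of polarity {polarity!r}")
    spectra.sort(key=lambda s: s.rt)
    return spectra


# ---------------------------------------------------------------------------
# Peak picking


class _Trace:
    __slots__ = ("rts", "mzs", "ints", "mz_sum", "int_sum")

    def __init__(self) -> None:
        self.rts: list = []
        self.mzs: list = []
        self.ints: list = []
        self.mz_sum = 0.0
        self.int_sum = 0.0

    def add(self, rt: float, mz: float, inten: float) -> None:
        self.rts.append(rt)
        self.mzs.append(mz)
        self.ints.append(inten)
        self.mz_sum += mz
        self.int_sum += inten

    @property
    def mean_mz(self) -> float:
        return self.mz_sum / len(self.mzs)


def _build_traces(spectra: Sequence[Spectrum], ppm: float, rt_gap_s: float):
    open_traces: List[_Trace] = []
    closed: List[_Trace] = []
    for spec in spectra:
        still_open = []
        for tr in open_traces:
            if spec.rt - tr.rts[-1] > rt_gap_s:
                closed.append(tr)
            else:
                still_open.append(tr)
        open_traces = still_open

        means = np.array([tr.mean_mz for tr in open_traces])
        claimed = set()
        for mz, inten in zip(spec.mz, spec.intensity):
            best, best_d = None, None
            if means.size:
                rel = np.abs(means - mz) / means * 1e6
                for j in np.flatnonzero(rel <= ppm):
                    if j in claimed:
                        continue
                    if best is None or rel[j] < best_d:
                        best, best_d = j, rel[j]
            if best is None:
                tr = _Trace()
                tr.add(spec.rt, mz, inten)
                open_traces.append(tr)
                means = np.append(means, mz)
            else:
                open_traces[best].add(spec.rt, mz, inten)
                claimed.add(best)
                means[best] = open_traces[best].mean_mz
    closed.extend(open_traces)
    return closed


def _detect_peaks(trace: _Trace, params: PeakPickingParams):
    """Return (apex_idx, region_slice) pairs of local-maximum runs."""
    inten = np.asarray(trace.ints)
    rts = np.asarray(trace.rts)
    n = inten.size
    assigned = np.zeros(n, dtype=bool)
    peaks = []
    order = np.argsort(inten)[::-1]
    for apex in order:
        if assigned[apex] or inten[apex] <= 0:
            continue
        lo = apex
        while (
            lo > 0
            and not assigned[lo - 1]
            and inten[lo - 1] <= inten[lo]
            and rts[apex] - rts[lo - 1] <= params.rt_peak_window_s
        ):
            lo -= 1
        hi = apex
        while (
            hi < n - 1
            and not assigned[hi + 1]
            and inten[hi + 1] <= inten[hi]
            and rts[hi + 1] - rts[apex] <= params.rt_peak_window_s
        ):
            hi += 1
        if hi - lo + 1 >= params.min_scans:
            assigned[lo : hi + 1] = True
            peaks.append((apex, slice(lo, hi + 1)))
    return peaks, assigned


def pick_features(
    spectra: Sequence[Spectrum],
    params: PeakPickingParams | None = None,
    sample_id: str = "",
) -> List[Feature]:
    """Detect chromatographic features from centroided MS1 spectra.

    Traces are grown scan-to-scan inside the ppm cluster window and broken
    at RT gaps; within each trace, local-maximum runs of at least
    ``min_scans`` points become peaks when the apex clears ``sn_min`` ×
    trace noise and ``sb_min`` × local baseline, and the apex intensity
    lies in the retained band. The feature m/z is the intensity-weighted
    mean over the run; the RT is the apex scan RT (a literal input centroid).
    """
    params = params or PeakPickingParams()
    spectra = sorted(spectra, key=lambda s: s.rt)
    if not spectra:
        return []
    polarity = spectra[0].polarity
    if any(s.polarity != polarity for s in spectra):
        raise ValueError("pick_features requires a single-polarity scan set")

    features: List[Feature] = []
    for trace in _build_traces(spectra, params.mz_cluster_ppm, params.rt_gap_s):
        inten = np.asarray(trace.ints)
        rts = np.asarray(trace.rts)
        mzs = np.asarray(trace.mzs)
        peaks, assigned = _detect_peaks(trace, params)
        if not peaks:
            continue
        nonpeak = inten[~assigned]
        noise = max(float(np.median(nonpeak)) if nonpeak.size else 0.0, 1.0)
        for apex, region in peaks:
            apex_int = float(inten[apex])
            lo, hi = region.start, region.stop
            edges = []
            if lo > 0:
                edges.append(inten[lo - 1])
            if hi < inten.size:
                edges.append(inten[hi])
            baseline = max(float(np.mean(edges)) if edges else 0.0, 1.0)
            if apex_int < params.sn_min * noise:
                continue
            if apex_int < params.sb_min * baseline:
                continue
            if not (params.min_intensity <= apex_int <= params.max_intensity):
                continue
            seg_i = inten[region]
            seg_mz = mzs[region]
            mz = float(np.average(seg_mz, weights=seg_i)) if seg_i.sum() else float(seg_mz[apex - lo])
            if params.intensity_measure == "area":
                reported = float(np.trapezoid(seg_i, rts[region])) if hi - lo > 1 else apex_int
            else:
                reported = apex_int
            features.append(
                Feature(mz=mz, rt=float(rts[apex]), intensity=reported,
                        polarity=polarity, sample_id=sample_id)
            )
    features.sort(key=lambda f: (f.mz, f.rt))
    return features


# ---------------------------------------------------------------------------
# Feature tables (the CSV bypass path)


def features_to_frame(features: Iterable[Feature]) -> pd.DataFrame:
    rows = [
        (f.sample_id, f.polarity, f.mz, f.rt, f.intensity) for f in features
    ]
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS)


def read_feature_table(path: str) -> pd.DataFrame:
    """Read a pre-picked feature list CSV (header required)."""
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing feature-list columns {missing}")
    if (df["mz"] <= 0).any():
        raise ValueError(f"{path}: non-positive m/z values")
    bad = set(df["polarity"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"{path}: invalid polarity values {sorted(bad)}")
    return df[FEATURE_COLUMNS].copy()


def write_feature_table(df: pd.DataFrame, path: str) -> None:
    df[FEATURE_COLUMNS].to_csv(path, index=False)
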