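"""Ground-truth simulation of a stable-isotope tracing experiment.

Emulates the two-arm acquisition design: an unlabeled identification
export (each molecule's M+0 ion at its nominal RT) and, per labeled
sample, an MS1 feature list carrying the planted isotopologue envelope of
every molecule — each M+n component at its theoretical m/z perturbed by
ppm-scale Gaussian jitter, with Gaussian RT jitter and lognormal intensity
noise — plus uniform decoy features and optional co-eluting interferers
placed at a fixed Th offset from a host molecule (the overlapping-lipid
scenario). ``evaluate`` scores search output against the planted truth.

Default jitter scales (1.5 ppm m/z, 0.14 s RT) reflect the mass and RT
reproducibility of a high-resolution Orbitrap platform; intensity noise
defaults to a 10% CV. The generator draws all randomness from one seeded
generator, with per-sample substreams derived by stable hashing of the
sample id so adding a sample never perturbs existing ones.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem import ion_mz, isotopomer_mz, get_adduct, monoisotopic_mass, parse_formula
from .msdata import FEATURE_COLUMNS, Spectrum
from .reference import parse_fatty_acids, parse_lipid_class

__all__ = [
    "SimulatedMolecule",
    "SimulationConfig",
    "GroundTruth",
    "SimulationResult",
    "simulate",
    "evaluate",
    "default_metabolite_panel",
    "overlap_scenario",
    "write_mzml",
    "spectra_from_features",
]


@dataclass
class SimulatedMolecule:
    """One planted molecule: identity, chromatography and labeling envelope."""

    name: str
    formula: str
    rt_s: float
    adduct: str
    polarity: str
    base_intensity: float
    envelope: Dict[int, float]
    mode: str = "metabolite"
    accession: str = ""

    def __post_init__(self) -> None:
        fracs = np.array(list(self.envelope.values()), dtype=float)
        if (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"{self.name}: envelope fractions must be >= 0 and sum to 1"
            )

    @property
    def ion_mz(self) -> float:
        return ion_mz(monoisotopic_mass(parse_formula(self.formula)), get_adduct(self.adduct))


@dataclass
class SimulationConfig:
    molecules: List[SimulatedMolecule]
    mz_jitter_ppm_sd: float = 1.5
    rt_jitter_sd_s: float = 0.14
    intensity_cv: float = 0.1
    n_decoys: int = 0
    decoy_mz_range: Tuple[float, float] = (100.0, 900.0)
    decoy_rt_range: Tuple[float, float] = (30.0, 900.0)
    interferer_pairs: List[Tuple[str, float, float, float]] = field(default_factory=list)
    sample_ids: List[str] = field(default_factory=lambda: ["S1"])
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mz_jitter_ppm_sd", "rt_jitter_sd_s", "intensity_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class GroundTruth:
    """Planted features per sample and the decoy list, for evaluation."""

    planted: pd.DataFrame  # sample_id, name, n, true_mz, true_rt, true_intensity
    decoys: pd.DataFrame   # sample_id, mz, rt_s, intensity, kind


@dataclass
class SimulationResult:
    metabolite_export: pd.DataFrame
    lipid_export: pd.DataFrame
    features: Dict[str, pd.DataFrame]
    truth: GroundTruth
    config: SimulationConfig


def _sample_rng(seed: int, sample_id: str) -> np.random.Generator:
    # substream keyed by a stable hash of the sample id; adding a sample
    # never perturbs the draws of existing ones
    return np.random.default_rng(
        np.random.SeedSequence([seed, zlib.crc32(sample_id.encode())])
    )


def simulate(config: SimulationConfig) -> SimulationResult:
    """Generate identification exports, labeled feature lists and truth."""
    met_rows, lip_rows = [], []
    for mol in config.molecules:
        if mol.mode == "metabolite":
            met_rows.append(
                (mol.name, mol.accession, mol.ion_mz, mol.rt_s, mol.polarity,
                 mol.adduct, mol.formula)
            )
        else:
            lip_rows.append(
                (mol.name, parse_lipid_class(mol.name),
                 "/".join(parse_fatty_acids(mol.name)), mol.formula, "A", 9.0,
                 mol.ion_mz, mol.rt_s, mol.adduct, mol.polarity)
            )
    metabolite_export = pd.DataFrame(
        met_rows,
        columns=["name", "accession", "mz", "rt", "polarity", "adduct", "formula"],
    )
    lipid_export = pd.DataFrame(
        lip_rows,
        columns=["LipidID", "Class", "FA", "Formula", "Grade", "m-score",
                 "CalcMz", "Rt", "Ion", "polarity"],
    )

    mol_by_name = {m.name: m for m in config.molecules}
    features: Dict[str, pd.DataFrame] = {}
    planted_rows, decoy_rows = [], []
    for sample_id in config.sample_ids:
        rng = _sample_rng(config.seed, sample_id)
        sigma = np.sqrt(np.log1p(config.intensity_cv**2))
        rows = []
        for mol in config.molecules:
            z = abs(get_adduct(mol.adduct).z)
            base = mol.ion_mz
            for n in sorted(mol.envelope):
                frac = mol.envelope[n]
                if frac <= 0:
                    continue
                mz_true = isotopomer_mz(base, n, z)
                mz = mz_true * (1.0 + rng.normal(0.0, config.mz_jitter_ppm_sd) * 1e-6)
                rt = mol.rt_s + rng.normal(0.0, config.rt_jitter_sd_s)
                inten = mol.base_intensity * frac * (
                    float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
                )
                rows.append((sample_id, mol.polarity, mz, rt, inten))
                planted_rows.append((sample_id, mol.name, n, mz, rt, inten))
        for _ in range(config.n_decoys):
            mz = rng.uniform(*config.decoy_mz_range)
            rt = rng.uniform(*config.decoy_rt_range)
            inten = 10 ** rng.uniform(4.0, 6.0)
            pol = str(rng.choice(["positive", "negative"]))
            rows.append((sample_id, pol, mz, rt, inten))
            decoy_rows.append((sample_id, mz, rt, inten, "uniform"))
        for name, offset_th, rt_offset, inten in config.interferer_pairs:
            host = mol_by_name[name]
            mz = host.ion_mz + offset_th
            rt = host.rt_s + rt_offset
            rows.append((sample_id, host.polarity, mz, rt, inten))
            decoy_rows.append((sample_id, mz, rt, inten, "interferer"))
        fdf = pd.DataFrame(rows, columns=["sample_id", "polarity", "mz", "rt_s", "intensity"])
        features[sample_id] = fdf.sort_values(["polarity", "mz"], kind="stable").reset_index(drop=True)

    truth = GroundTruth(
        planted=pd.DataFrame(
            planted_rows,
            columns=["sample_id", "name", "n", "true_mz", "true_rt", "true_intensity"],
        ),
        decoys=pd.DataFrame(
            decoy_rows, columns=["sample_id", "mz", "rt_s", "intensity", "kind"]
        ),
    )
    return SimulationResult(metabolite_export, lipid_export, features, truth, config)


def evaluate(
    hits: pd.DataFrame,
    truth: GroundTruth,
    mz_tol: float = 1e-6,
    rt_tol: float = 1e-4,
) -> dict:
    """Score search hits against the planted ground truth.

    A hit is a true positive iff its (sample, molecule, n) was planted and
    the matched feature *is* the planted one (m/z and RT agree within
    round-trip tolerance) — matching a decoy or interferer at the right
    annotation still counts as a false positive. With zero hits, precision
    is reported as 1.0 with a ``zero_hits`` flag.
    """
    planted = truth.planted
    key_cols = ["sample_id", "name", "n"]
    planted_idx = planted.set_index(key_cols)

    tp = fp = 0
    matched_keys = set()
    confusion = []
    for _, h in hits.iterrows():
        key = (h["sample_id"], h["Metabolite/Lipid"], int(h["n"]))
        ok = False
        if key in planted_idx.index:
            row = planted_idx.loc[key]
            ok = (
                abs(h["mz2"] - row["true_mz"]) <= mz_tol * max(1.0, row["true_mz"])
                and abs(h["rt2"] - row["true_rt"]) <= rt_tol
            )
        if ok:
            tp += 1
            matched_keys.add(key)
        else:
            fp += 1
        confusion.append((*key, bool(ok)))

    n_planted = len(planted)
    fn = n_planted - len(matched_keys)
    zero_hits = len(hits) == 0
    precision = 1.0 if zero_hits else tp / (tp + fp)
    recall = (len(matched_keys) / n_planted) if n_planted else 1.0
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "n_planted": n_planted,
        "precision": precision,
        "recall": recall,
        "zero_hits": zero_hits,
        "confusion": pd.DataFrame(
            confusion, columns=["sample_id", "name", "n", "true_positive"]
        ),
    }


# ---------------------------------------------------------------------------
# Canned scenarios


def default_metabolite_panel(
    n_molecules: int = 50,
    seed: int = 0,
    rt_range: Tuple[float, float] = (60.0, 840.0),
) -> List[SimulatedMolecule]:
    """A random panel of plausible polar metabolites with labeled envelopes.

    Formulas draw 3–30 carbons with H/N/O/P in biochemically sensible
    proportions; each envelope keeps M+0 plus 2–4 heavy components at
    label counts up to min(C, 10), with random fractions normalized to 1.
    """
    rng = np.random.default_rng(seed)
    molecules = []
    for i in range(n_molecules):
        c = int(rng.integers(3, 31))
        h = int(rng.integers(c, 2 * c + 3))
        n_at = int(rng.integers(0, 4))
        o = int(rng.integers(1, 9))
        p = int(rng.integers(0, 3))
        formula = f"C{c}H{h}" + (f"N{n_at}" if n_at else "") + f"O{o}" + (f"P{p}" if p else "")
        polarity = "negative" if rng.random() < 0.5 else "positive"
        cap = min(c, 10)
        k = int(rng.integers(2, min(4, cap) + 1))
        heavy_ns = rng.choice(np.arange(1, cap + 1), size=k, replace=False)
        w = rng.dirichlet(np.ones(k + 1))
        envelope = {0: float(w[0])}
        envelope.update({int(n): float(w[j + 1]) for j, n in enumerate(heavy_ns)})
        molecules.append(
            SimulatedMolecule(
                name=f"MET{i:03d}",
                formula=formula,
                rt_s=float(rng.uniform(*rt_range)),
                adduct="-H" if polarity == "negative" else "+H",
                polarity=polarity,
                base_intensity=float(10 ** rng.uniform(5.0, 6.5)),
                envelope=envelope,
            )
        )
    return molecules


def overlap_scenario(seed: int = 0, include_planted_heavy: bool = True) -> SimulationConfig:
    """The co-eluting-lipid overlap scenario.

    A dipalmitoyl phosphatidylcholine formate ion (m/z 778.56) carries a
    heavily labeled envelope reaching M+26 (m/z 804.647); a co-eluting
    heavier lipid's unlabeled ion sits 26.0157 Th above the host M+0 —
    only 0.0716 Th (≈ 89 ppm) from the M+26 candidate, far outside a
    10 ppm gate yet trivially inside any RT window. With
    ``include_planted_heavy=False`` the true M+26 feature is withheld so
    any hit at M+26 must be the interferer.
    """
    envelope = {0: 0.35, 3: 0.20, 16: 0.20, 26: 0.25}
    if not include_planted_heavy:
        total = sum(v for n, v in envelope.items() if n != 26)
        envelope = {n: v / total for n, v in envelope.items() if n != 26}
    host = SimulatedMolecule(
        name="PC(16:0/16:0)",
        formula="C40H80NO8P",
        rt_s=600.0,
        adduct="+HCOO",
        polarity="negative",
        base_intensity=5e5,
        envelope=envelope,
        mode="lipid",
    )
    # heavier co-eluting lipid M+0: +C2H2 relative to the host neutral
    offset = monoisotopic_mass(parse_formula("C2H2"))
    return SimulationConfig(
        molecules=[host],
        interferer_pairs=[("PC(16:0/16:0)", offset, 0.0, 8e5)],
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Minimal spectra synthesis and mzML writing (end-to-end tests)


def spectra_from_features(
    features: pd.DataFrame,
    polarity: str,
    rt_start: float = 0.0,
    rt_end: float | None = None,
    scan_interval_s: float = 1.0,
    peak_sd_s: float = 3.0,
) -> List[Spectrum]:
    """Render a feature list into Gaussian-EIC centroided MS1 scans.

    Each feature becomes a Gaussian elution profile (apex = feature
    intensity at the feature RT) sampled at the scan grid, at a constant
    centroid m/z.
    """
    sub = features[features["polarity"] == polarity]
    if rt_end is None:
        rt_end = float(sub["rt_s"].max() + 5 * peak_sd_s) if len(sub) else 60.0
    times = np.arange(rt_start, rt_end + scan_interval_s / 2, scan_interval_s)
    spectra = []
    mzs = sub["mz"].to_numpy()
    rts = sub["rt_s"].to_numpy()
    intens = sub["intensity"].to_numpy()
    for t in times:
        amp = intens * np.exp(-0.5 * ((t - rts) / peak_sd_s) ** 2)
        keep = amp >= 1.0
        spectra.append(Spectrum(float(t), polarity, 1, mzs[keep], amp[keep]))
    return spectra


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
  <cvList count="1">
    <cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
  </cvList>
  <fileDescription><fileContent>
    <cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/>
  </fileContent></fileDescription>
  <run id="run">
    <spectrumList count="{count}">
"""

_MZML_FOOTER = """    </spectrumList>
  </run>
</mzML>
"""


def _b64_doubles(values: np.ndarray) -> str:
    raw = struct.pack(f"<{len(values)}d", *map(float, values))
    return base64.b64encode(raw).decode()


def write_mzml(spectra: Sequence[Spectrum], path: str) -> None:
    """Write spectra as minimal centroided mzML 1.1 (uncompressed, 64-bit)."""
    pol_param = {
        "positive": '<cvParam cvRef="MS" accession="MS:1000130" name="positive scan" value=""/>',
        "negative": '<cvParam cvRef="MS" accession="MS:1000129" name="negative scan" value=""/>',
    }
    chunks = [_MZML_HEADER.format(count=len(spectra))]
    for i, s in enumerate(spectra):
        mz_b64 = _b64_doubles(s.mz)
        int_b64 = _b64_doubles(s.intensity)
        chunks.append(f"""      <spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{s.mz.size}">
        <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>
        <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
        {pol_param[s.polarity]}
        <scanList count="1">
          <scan>
            <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt}" unitCvRef="UO" unitAccession="UO:0000010" unitName="second"/>
          </scan>
        </scanList>
        <binaryDataArrayList count="2">
          <binaryDataArray encodedLength="{len(mz_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>
            <binary>{mz_b64}</binary>
          </binaryDataArray>
          <binaryDataArray encodedLength="{len(int_b64)}">
            <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
            <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
            <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>
            <binary>{int_b64}</binary>
          </binaryDataArray>
        </binaryDataArrayList>
      </spectrum>
""")
    chunks.append(_MZML_FOOTER)
    with open(path, "w") as fh:
        fh.write("".join(chunks))
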