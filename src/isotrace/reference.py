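"""Reference-list construction and theoretical isotopomer expansion.

Imports identification exports from unlabeled samples — a metabolite table
(Scaffold-Elements-like dialect) and a lipid table (LipidSearch-like
dialect, filtered by identification grade and m-score) — pools them into a
single reference list, and expands each reference ion into its theoretical
M+0…M+N isotopomer ladder.

Isotopomer caps reflect molecule size: polar metabolites go up to M+10 and
lipids up to M+40; when an elemental formula is available the ladder is
additionally capped at the molecule's carbon count (a molecule cannot carry
more ¹³C labels than carbon atoms). M+0 is generated alongside the heavy
candidates so that the unlabeled isotopomer can be located in the labeled
run, which the labeling-ratio denominator requires.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chem import Adduct, ChemicalFormula, get_adduct, isotopomer_mz, parse_formula

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceEntry",
    "IsotopomerCandidate",
    "load_metabolite_export",
    "load_lipid_export",
    "pool_references",
    "build_candidates",
    "references_to_frame",
    "load_reference_pool",
    "parse_fatty_acids",
]

N_MAX_METABOLITE = 10
N_MAX_LIPID = 40


@dataclass
class ReferenceEntry:
    """One identified unlabeled ion anchoring an isotopomer trace."""

    ref_id: str
    name: str
    mode: str  # "metabolite" | "lipid"
    mz: float
    rt: float
    polarity: str
    adduct: Adduct
    z: int = 1
    accession: str = ""
    formula: Optional[ChemicalFormula] = None
    lipid_class: str = ""
    fatty_acids: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError(f"{self.ref_id}: non-positive m/z")
        if self.z < 1:
            raise ValueError(f"{self.ref_id}: charge magnitude must be >= 1")
        if self.mode not in ("metabolite", "lipid"):
            raise ValueError(f"{self.ref_id}: invalid mode {self.mode!r}")
        if self.mode == "lipid" and not self.lipid_class:
            raise ValueError(f"{self.ref_id}: lipid entry without lipid_class")
        if self.polarity != self.adduct.polarity:
            raise ValueError(
                f"{self.ref_id}: polarity {self.polarity!r} does not match "
                f"adduct {self.adduct.name!r}"
            )


@dataclass(frozen=True)
class IsotopomerCandidate:
    """A theoretical (reference, M+n) ion with its computed m/z."""

    ref_id: str
    n: int
    theoretical_mz: float

    @property
    def annotation(self) -> str:
        return f"M+{self.n}"


_FA_CHAIN = re.compile(r"\b([dtme]?-?\d{1,2}:\d{1,2})(?:[^/)]*)")


def parse_fatty_acids(lipid_id: str) -> List[str]:
    """Extract fatty-acid chain tokens from a LipidSearch-style LipidID.

    ``"PC(16:0/18:1)"`` → ``["16:0", "18:1"]``. Duplicated chains are kept
    (the per-chain aggregation later deduplicates per lipid).
    """
    m = re.search(r"\(([^()]*)\)", lipid_id)
    if not m:
        return []
    chains = []
    for part in m.group(1).split("/"):
        cm = re.search(r"\d{1,2}:\d{1,2}", part)
        if cm:
            chains.append(cm.group(0))
    return chains


def parse_lipid_class(lipid_id: str) -> str:
    m = re.match(r"\s*([A-Za-z0-9]+)\s*\(", lipid_id)
    return m.group(1) if m else lipid_id.strip()


def _default_adduct(polarity: str) -> str:
    return "+H" if polarity == "positive" else "-H"


def _resolve_columns(df: pd.DataFrame, aliases: Mapping[str, Sequence[str]],
                     required: Sequence[str], path: str) -> Mapping[str, str]:
    lower = {c.lower(): c for c in df.columns}
    resolved = {}
    for canon, names in aliases.items():
        for name in names:
            if name.lower() in lower:
                resolved[canon] = lower[name.lower()]
                break
    missing = [c for c in required if c not in resolved]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    return resolved


METABOLITE_ALIASES = {
    "name": ["name", "metabolite", "compound"],
    "accession": ["accession", "id", "hmdb"],
    "mz": ["mz", "m/z", "observed_mz"],
    "rt": ["rt", "rt_s", "retention_time"],
    "polarity": ["polarity", "ion_mode", "mode"],
    "adduct": ["adduct", "ion"],
    "charge": ["charge", "z"],
    "formula": ["formula", "chemical_formula"],
    "intensity": ["intensity", "abundance"],
}

LIPID_ALIASES = {
    "lipid_id": ["lipidid", "lipid_id", "lipid"],
    "lipid_class": ["class", "lipidclass"],
    "fa": ["fa", "fattyacid", "fatty_acids"],
    "formula": ["formula", "lipidform"],
    "grade": ["grade", "grades"],
    "mscore": ["m-score", "mscore", "m_score"],
    "mz": ["calcmz", "obsmz", "mz", "m/z"],
    "rt": ["rt", "rt_s", "retention_time"],
    "adduct": ["ion", "adduct"],
    "polarity": ["polarity", "ion_mode", "mode"],
}


def load_metabolite_export(
    path: str,
    extra_adducts: Mapping[str, Adduct] | None = None,
    column_aliases: Mapping[str, Sequence[str]] | None = None,
) -> List[ReferenceEntry]:
    """Load a metabolite identification export (delimited text).

    Requires at least name, mz, rt and polarity columns; adduct and charge
    default to +H/−H (by polarity) at z = 1. Duplicate (name, adduct,
    polarity) rows keep the highest-intensity occurrence (first on ties),
    with a log notice.
    """
    df = pd.read_csv(path)
    aliases = dict(METABOLITE_ALIASES)
    if column_aliases:
        aliases.update(column_aliases)
    cols = _resolve_columns(df, aliases, ["name", "mz", "rt", "polarity"], path)

    entries: List[ReferenceEntry] = []
    seen: dict = {}
    for i, row in df.iterrows():
        polarity = str(row[cols["polarity"]]).strip().lower()
        adduct_name = (
            str(row[cols["adduct"]]).strip()
            if "adduct" in cols and pd.notna(row[cols["adduct"]])
            else _default_adduct(polarity)
        )
        adduct = get_adduct(adduct_name, extra_adducts)
        formula = None
        if "formula" in cols and pd.notna(row[cols["formula"]]) and str(row[cols["formula"]]).strip():
            formula = parse_formula(str(row[cols["formula"]]))
        entry = ReferenceEntry(
            ref_id=f"M{i:05d}",
            name=str(row[cols["name"]]).strip(),
            mode="metabolite",
            mz=float(row[cols["mz"]]),
            rt=float(row[cols["rt"]]),
            polarity=polarity,
            adduct=adduct,
            z=abs(int(row[cols["charge"]])) if "charge" in cols and pd.notna(row.get(cols.get("charge"))) else abs(adduct.z),
            accession=str(row[cols["accession"]]).strip() if "accession" in cols and pd.notna(row[cols["accession"]]) else "",
            formula=formula,
        )
        key = (entry.name, entry.adduct.name, entry.polarity)
        inten = float(row[cols["intensity"]]) if "intensity" in cols and pd.notna(row.get(cols.get("intensity"))) else float("nan")
        if key in seen:
            prev_inten, prev_idx = seen[key]
            logger.info("duplicate metabolite row for %s; keeping higher intensity", key)
            if not np.isnan(inten) and (np.isnan(prev_inten) or inten > prev_inten):
                entries[prev_idx] = entry
                seen[key] = (inten, prev_idx)
            continue
        seen[key] = (inten, len(entries))
        entries.append(entry)
    return entries


GRADE_ORDER = "ABCD"


def load_lipid_export(
    path: str,
    grade_max: str = "C",
    mscore_min: float = 5.0,
    extra_adducts: Mapping[str, Adduct] | None = None,
    column_aliases: Mapping[str, Sequence[str]] | None = None,
) -> List[ReferenceEntry]:
    """Load a LipidSearch-style lipid export, applying identification filters.

    Rows are retained iff grade ∈ {A, …, grade_max} and m-score ≥
    ``mscore_min`` (defaults C and 5.0). Fatty-acid chains are parsed from
    the LipidID; rows with unparseable grades are dropped with a warning.
    """
    if grade_max not in GRADE_ORDER:
        raise ValueError(f"grade_max must be one of {GRADE_ORDER!r}")
    df = pd.read_csv(path)
    if df.empty:
        return []
    aliases = dict(LIPID_ALIASES)
    if column_aliases:
        aliases.update(column_aliases)
    cols = _resolve_columns(
        df, aliases, ["lipid_id", "grade", "mscore", "mz", "rt", "polarity"], path
    )
    allowed = set(GRADE_ORDER[: GRADE_ORDER.index(grade_max) + 1])
    entries: List[ReferenceEntry] = []
    for i, row in df.iterrows():
        grade = str(row[cols["grade"]]).strip().upper()
        if grade not in set(GRADE_ORDER):
            logger.warning("%s row %d: unparseable grade %r; dropped", path, i, grade)
            continue
        if grade not in allowed or float(row[cols["mscore"]]) < mscore_min:
            continue
        lipid_id = str(row[cols["lipid_id"]]).strip()
        polarity = str(row[cols["polarity"]]).strip().lower()
        adduct_name = (
            str(row[cols["adduct"]]).strip()
            if "adduct" in cols and pd.notna(row[cols["adduct"]])
            else _default_adduct(polarity)
        )
        adduct = get_adduct(adduct_name, extra_adducts)
        formula = None
        if "formula" in cols and pd.notna(row[cols["formula"]]) and str(row[cols["formula"]]).strip():
            formula = parse_formula(str(row[cols["formula"]]))
        lipid_class = (
            str(row[cols["lipid_class"]]).strip()
            if "lipid_class" in cols and pd.notna(row[cols["lipid_class"]])
            else parse_lipid_class(lipid_id)
        )
        entries.append(
            ReferenceEntry(
                ref_id=f"L{i:05d}",
                name=lipid_id,
                mode="lipid",
                mz=float(row[cols["mz"]]),
                rt=float(row[cols["rt"]]),
                polarity=polarity,
                adduct=adduct,
                z=abs(adduct.z),
                formula=formula,
                lipid_class=lipid_class,
                fatty_acids=parse_fatty_acids(lipid_id),
            )
        )
    return entries


def pool_references(*lists: Iterable[ReferenceEntry]) -> List[ReferenceEntry]:
    """Pool identification lists into one deduplicated reference list.

    Duplicates share (name, adduct, polarity); their m/z and RT become the
    group medians. ref_ids are reassigned stably, sorted by polarity then
    m/z, so pooling is idempotent and order-insensitive up to relabeling.
    """
    if not lists:
        raise ValueError("pool_references needs at least one list")
    groups: dict = {}
    for lst in lists:
        for e in lst:
            groups.setdefault((e.name, e.adduct.name, e.polarity), []).append(e)
    pooled: List[ReferenceEntry] = []
    for key, members in groups.items():
        base = members[0]
        mz = float(np.median([m.mz for m in members]))
        rt = float(np.median([m.rt for m in members]))
        if len(members) > 1:
            logger.info(
                "pooled %d occurrences of %s: median m/z %.5f, median RT %.2f",
                len(members), key, mz, rt,
            )
        pooled.append(
            ReferenceEntry(
                ref_id="tmp", name=base.name, mode=base.mode, mz=mz, rt=rt,
                polarity=base.polarity, adduct=base.adduct, z=base.z,
                accession=next((m.accession for m in members if m.accession), ""),
                formula=next((m.formula for m in members if m.formula), None),
                lipid_class=base.lipid_class, fatty_acids=list(base.fatty_acids),
            )
        )
    pooled.sort(key=lambda e: (e.polarity, e.mz, e.name))
    for i, e in enumerate(pooled):
        e.ref_id = f"R{i:05d}"
    return pooled


def build_candidates(
    refs: Sequence[ReferenceEntry],
    n_max_metabolite: int = N_MAX_METABOLITE,
    n_max_lipid: int = N_MAX_LIPID,
    cap_by_formula: bool = True,
) -> List[IsotopomerCandidate]:
    """Expand references into theoretical M+0…M+N isotopomer candidates.

    N is the mode cap (10 for metabolites, 40 for lipids), reduced to the
    formula's carbon count when ``cap_by_formula`` is on and a formula is
    known. M+0 is included so the unlabeled isotopomer is searched in the
    labeled run (needed for the labeling-ratio denominator).
    """
    if not len(refs):
        raise ValueError("build_candidates requires a non-empty reference list")
    out: List[IsotopomerCandidate] = []
    for ref in refs:
        cap = n_max_metabolite if ref.mode == "metabolite" else n_max_lipid
        if cap_by_formula and ref.formula is not None:
            cap = min(cap, ref.formula.carbon_count)
        for n in range(cap + 1):
            out.append(
                IsotopomerCandidate(
                    ref_id=ref.ref_id,
                    n=n,
                    theoretical_mz=isotopomer_mz(ref.mz, n, ref.z),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Round-trip CSV for the pooled reference list

REF_COLUMNS = [
    "ref_id", "name", "mode", "mz", "rt", "polarity", "adduct", "z",
    "accession", "formula", "lipid_class", "fatty_acids",
]


def references_to_frame(refs: Sequence[ReferenceEntry]) -> pd.DataFrame:
    rows = [
        (
            e.ref_id, e.name, e.mode, e.mz, e.rt, e.polarity, e.adduct.name,
            e.z, e.accession, str(e.formula) if e.formula else "",
            e.lipid_class, "/".join(e.fatty_acids),
        )
        for e in refs
    ]
    return pd.DataFrame(rows, columns=REF_COLUMNS)


def load_reference_pool(
    path: str, extra_adducts: Mapping[str, Adduct] | None = None
) -> List[ReferenceEntry]:
    """Read back a pooled reference list written by ``references_to_frame``."""
    df = pd.read_csv(path, keep_default_na=False)
    missing = [c for c in REF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing reference-pool columns {missing}")
    refs = []
    for _, row in df.iterrows():
        refs.append(
            ReferenceEntry(
                ref_id=str(row["ref_id"]),
                name=str(row["name"]),
                mode=str(row["mode"]),
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                polarity=str(row["polarity"]),
                adduct=get_adduct(str(row["adduct"]), extra_adducts),
                z=int(row["z"]),
                accession=str(row["accession"]),
                formula=parse_formula(str(row["formula"])) if str(row["formula"]) else None,
                lipid_class=str(row["lipid_class"]),
                fatty_acids=[t for t in str(row["fatty_acids"]).split("/") if t],
            )
        )
    return refs
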