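import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def toy_metabolite_csv(tmp_path):
    """Three-metabolite identification export (both polarities)."""
    df = pd.DataFrame(
        {
            "name": ["glycine", "lactate", "UTP"],
            "accession": ["HMDB0000123", "HMDB0000190", "HMDB0000285"],
            "mz": [76.0393, 89.0244, 482.9606],
            "rt": [120.0, 150.0, 310.0],
            "polarity": ["positive", "negative", "negative"],
            "adduct": ["+H", "-H", "-H"],
            "formula": ["C2H5NO2", "C3H6O3", "C9H15N2O15P3"],
        }
    )
    path = tmp_path / "metabolites.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def toy_lipid_csv(tmp_path):
    """Five-lipid export with mixed grades and m-scores."""
    df = pd.DataFrame(
        {
            "LipidID": [
                "PC(16:0/16:0)", "PC(16:0/18:1)", "TG(16:0/18:1/18:1)",
                "LPC(16:0)", "PE(18:0/20:4)",
            ],
            "Class": ["PC", "PC", "TG", "LPC", "PE"],
            "FA": ["16:0/16:0", "16:0/18:1", "16:0/18:1/18:1", "16:0", "18:0/20:4"],
            "Formula": ["C40H80NO8P", "C42H82NO8P", "C55H102O6", "C24H50NO7P", "C43H78NO8P"],
            "Grade": ["A", "B", "C", "D", "A"],
            "m-score": [9.0, 6.0, 5.0, 9.0, 3.0],
            "CalcMz": [778.5598, 804.5755, 876.8020, 540.3300, 766.5392],
            "Rt": [600.0, 620.0, 900.0, 300.0, 640.0],
            "Ion": ["+HCOO", "+HCOO", "+NH4", "+HCOO", "-H"],
            "polarity": ["negative", "negative", "positive", "negative", "negative"],
        }
    )
    path = tmp_path / "lipids.csv"
    df.to_csv(path, index=False)
    return path


@pytest.fixture
def feature_frame():
    """Small single-sample negative-mode feature list."""
    return pd.DataFrame(
        {
            "sample_id": ["S1"] * 4,
            "polarity": ["negative"] * 4,
            "mz": [482.9606, 483.9641, 487.9774, 600.1234],
            "rt_s": [310.0, 310.1, 309.9, 500.0],
            "intensity": [1e5, 4e4, 9e5, 2e5],
        }
    )


def random_match_instance(rng, n_refs=20, n_per_ref=10, n_features=2000):
    """A random matching problem mixing planted and background features."""
    from isotrace.chem import get_adduct
    from isotrace.reference import ReferenceEntry, build_candidates

    refs = [
        ReferenceEntry(
            ref_id=f"R{i:04d}",
            name=f"mol{i}",
            mode="metabolite",
            mz=float(rng.uniform(100, 900)),
            rt=float(rng.uniform(60, 900)),
            polarity="negative",
            adduct=get_adduct("-H"),
        )
        for i in range(n_refs)
    ]
    candidates = build_candidates(refs, n_max_metabolite=n_per_ref - 1,
                                  cap_by_formula=False)
    rows = []
    # background features across the m/z / RT plane
    n_planted = min(len(candidates), n_features // 4)
    for cand in rng.choice(len(candidates), size=n_planted, replace=False):
        c = candidates[int(cand)]
        ref = refs[int(c.ref_id[1:])]
        # spread deviations across gate and cutoff boundaries
        mz = c.theoretical_mz * (1 + rng.normal(0, 6) * 1e-6)
        rt = ref.rt + rng.normal(0, 0.5)
        rows.append((mz, rt, 10 ** rng.uniform(4, 7)))
    while len(rows) < n_features:
        rows.append(
            (rng.uniform(100, 901), rng.uniform(0, 1000), 10 ** rng.uniform(4, 7))
        )
    fdf = pd.DataFrame(rows, columns=["mz", "rt_s", "intensity"])
    fdf["sample_id"] = "S1"
    fdf["polarity"] = "negative"
    return refs, candidates, fdf


def brute_force_match(candidates, refs, fdf, params):
    """Exhaustive O(C×F) reference search: same gates, score and tie rules."""
    from isotrace.matching import score as score_fn

    ref_map = {r.ref_id: r for r in refs}
    order = np.argsort(fdf["mz"].to_numpy(), kind="stable")
    mz = fdf["mz"].to_numpy()[order]
    rt = fdf["rt_s"].to_numpy()[order]
    inten = fdf["intensity"].to_numpy()[order]
    rt_scale = 60.0 if params.rt_unit == "minutes" else 1.0
    hits = []
    for c in candidates:
        ref = ref_map[c.ref_id]
        th = c.theoretical_mz
        ok = (np.abs(mz - th) <= th * params.mz_window_ppm * 1e-6) & (
            np.abs((rt - ref.rt) / rt_scale) <= params.rt_window
        )
        idx = np.flatnonzero(ok)
        if not idx.size:
            continue
        s = np.atleast_1d(
            score_fn(mz[idx] - th, (rt[idx] - ref.rt) / rt_scale,
                     params.beta, params.score_form)
        )
        best = np.lexsort((np.abs(mz[idx] - th), -inten[idx], -s))[0]
        if s[best] < params.score_min:
            continue
        j = idx[best]
        hits.append((c.ref_id, c.n, mz[j], rt[j], float(s[best])))
    return set(hits)


def hits_as_set(df):
    return {
        (r["ref_id"], int(r["n"]), r["mz2"], r["rt2"], r["Score"])
        for _, r in df.iterrows()
    }
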