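import numpy as np
import pandas as pd
import pytest

import soygp


@pytest.fixture(scope="session")
def toy_qc_matrix() -> soygp.GenotypeMatrix:
    """4 samples × 5 markers: one monomorphic, one half-missing, three clean.

    m1 monomorphic (MAF 0), m2 50% missing, m3/m4/m5 polymorphic with
    MAF 0.5 / 0.125 / 0.25 — so default QC retains exactly {m3, m4, m5}.
    """
    nan = np.nan
    dosage = np.array([
        # m1  m2   m3  m4  m5
        [0.0, 0.0, 0.0, 0.0, 0.0],
        [0.0, 2.0, 1.0, 0.0, 0.0],
        [0.0, nan, 1.0, 0.0, 1.0],
        [0.0, nan, 2.0, 1.0, 1.0],
    ])
    return soygp.GenotypeMatrix(
        sample_ids=np.array(["s1", "s2", "s3", "s4"], dtype=object),
        marker_ids=np.array(["m1", "m2", "m3", "m4", "m5"], dtype=object),
        chrom=np.array(["1"] * 5, dtype=object),
        pos=np.arange(1, 6),
        dosage=dosage,
    )


@pytest.fixture(scope="session")
def two_cluster_sim():
    """Small two-cluster collection with phenotypes, BLUEs and truth.

    Panels A (cluster I) and E (cluster II) at between-cluster Fst 0.3,
    two traits with QTL-effect correlation −0.7, line-mean h² 0.9.
    """
    cfg = soygp.SimPanelConfig(
        n_markers=600,
        panel_sizes={"A": 120, "E": 120},
        cluster_assignment={"A": "I", "E": "II"},
        fst_within_cluster=0.02,
        fst_between_cluster=0.30,
        seed=11,
    )
    g, panels, mmap = soygp.simulate_founder_panels(cfg)
    arch = soygp.TraitArchitecture(n_qtl=120)
    effects = soygp.assign_qtl_effects(g, arch, seed=12)
    phen, truth = soygp.simulate_phenotypes(g, effects, arch, seed=13)
    blues = soygp.compute_blues(phen)
    return {
        "geno": g, "panels": panels, "map": mmap, "arch": arch,
        "effects": effects, "phenotypes": phen, "truth": truth, "blues": blues,
    }


@pytest.fixture(scope="session")
def balanced_2x2x2() -> pd.DataFrame:
    rows = [
        ("L1", "E1", "R1", 10), ("L1", "E1", "R2", 12),
        ("L1", "E2", "R1", 14), ("L1", "E2", "R2", 16),
        ("L2", "E1", "R1", 20), ("L2", "E1", "R2", 18),
        ("L2", "E2", "R1", 22), ("L2", "E2", "R2", 26),
    ]
    df = pd.DataFrame(rows, columns=["line", "env", "rep", "value"])
    df["trait"] = "oil"
    return df[["line", "env", "rep", "trait", "value"]].astype({"value": float})
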