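"""Synthetic cohort generator: determinism, Poisson marginals, clustering."""

import numpy as np
import pandas as pd
import pytest

from tmespatial import write_cell_table
from tmespatial.io import Stratum, build_patients, stratify_cohort_by_mean
from tmespatial.spatial import nn_distances
from tmespatial.synthetic import (
    AttractionRule,
    StratumParams,
    SyntheticConfig,
    default_config,
    generate_cohort,
    null_config,
    sample_clustered_core,
    sample_csr_core,
)

TH = "TCELL_HELPER"
APC = "APC"


def test_cohort_counting_and_shape():
    cfg = default_config(seed=7, n_patients=10, cores_per_patient=3)
    patients, truth = generate_cohort(cfg)
    assert len(patients) == 10
    assert sum(len(p.cores) for p in patients) == 30
    assert len(truth) == 10
    assert set(truth["latent_stratum"]) <= {"HIGH", "LOW"}
    for p in patients:
        hladr = {c.hladr_area_pct for c in p.cores}
        assert len(hladr) == 1  # HLA-DR drawn per patient, copied to cores


def test_same_seed_gives_byte_identical_tables(tmp_path):
    cfg = default_config(seed=42, n_patients=4)
    a, _ = generate_cohort(cfg)
    b, _ = generate_cohort(cfg)
    pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
    write_cell_table([c for p in a for c in p.cores], pa)
    write_cell_table([c for p in b for c in p.cores], pb)
    assert pa.read_bytes() == pb.read_bytes()


def test_different_seeds_differ():
    a, _ = generate_cohort(default_config(seed=1, n_patients=2))
    b, _ = generate_cohort(default_config(seed=2, n_patients=2))
    assert not a[0].cores[0].cells.equals(b[0].cores[0].cells)


def test_all_cells_inside_disc():
    cfg = default_config(seed=3, n_patients=3)
    patients, _ = generate_cohort(cfg)
    for p in patients:
        for core in p.cores:
            r = np.hypot(core.cells["x"], core.cells["y"])
            assert (r <= cfg.core_radius + 1e-9).all()


def test_csr_counts_match_poisson_mean():
    """Mean count over 500 seeds within 3 SE of lambda*pi*R^2 ~ 282.7."""
    lam, R = 0.001, 300.0
    expected = lam * np.pi * R**2
    counts = [
        sample_csr_core({"OTHER": lam}, R, seed).n_cells for seed in range(500)
    ]
    se = np.sqrt(expected / 500)
    assert abs(np.mean(counts) - expected) < 3 * se


def test_csr_markers_consistent_with_phenotype():
    core = sample_csr_core({"TCELL_CTL": 5e-4, "APC": 5e-4}, 300.0, seed=0)
    ctl = core.cells[core.cells.phenotype == "TCELL_CTL"]
    assert (ctl["CD3"] == 1).all() and (ctl["CD8"] == 1).all()
    apc = core.cells[core.cells.phenotype == "APC"]
    assert (apc["CD3"] == 0).all() and (apc["CD163"] == 1).all()


def _clustered_params(sigma, frac):
    return StratumParams(
        densities={TH: 2e-4, APC: 3e-4},
        attraction={(TH, APC): AttractionRule(sigma, frac)},
    )


def _mean_th_apc_nn(core):
    th = core.cells[core.cells.phenotype == TH][["x", "y"]].to_numpy()
    apc = core.cells[core.cells.phenotype == APC][["x", "y"]].to_numpy()
    if len(th) == 0 or len(apc) == 0:
        return None
    return nn_distances(th, apc).mean()


def test_attraction_shortens_nn_distances():
    """sigma=10, all offspring clustered: Th->APC nn distance below the CSR
    configuration in >=95 of 100 seeds."""
    wins = 0
    for seed in range(100):
        clustered = sample_clustered_core(_clustered_params(10.0, 1.0), 300.0, seed)
        csr = sample_clustered_core(_clustered_params(10.0, 0.0), 300.0, seed)
        a, b = _mean_th_apc_nn(clustered), _mean_th_apc_nn(csr)
        if a is not None and b is not None and a < b:
            wins += 1
    assert wins >= 95


def test_huge_sigma_recovers_csr():
    """sigma >= 10 R: displaced offspring are uniform-ish; mean nn matches the
    CSR configuration within Monte-Carlo error over 50 seeds."""
    vals_big, vals_csr = [], []
    for seed in range(50):
        big = sample_clustered_core(_clustered_params(3000.0, 1.0), 300.0, seed)
        csr = sample_clustered_core(_clustered_params(3000.0, 0.0), 300.0, seed)
        a, b = _mean_th_apc_nn(big), _mean_th_apc_nn(csr)
        if a is not None and b is not None:
            vals_big.append(a)
            vals_csr.append(b)
    diff = np.mean(vals_big) - np.mean(vals_csr)
    se = np.sqrt(np.var(vals_big) / len(vals_big) + np.var(vals_csr) / len(vals_csr))
    assert abs(diff) < 4 * se


def test_clustering_conserves_counts():
    """Counts are drawn before positions: changing sigma at a fixed seed moves
    cells but never adds or removes them."""
    for seed in range(10):
        a = sample_clustered_core(_clustered_params(5.0, 1.0), 300.0, seed)
        b = sample_clustered_core(_clustered_params(500.0, 1.0), 300.0, seed)
        ca = a.cells.phenotype.value_counts().to_dict()
        cb = b.cells.phenotype.value_counts().to_dict()
        assert ca == cb


def test_zero_parents_falls_back_to_csr():
    params = StratumParams(
        densities={TH: 2e-4, APC: 0.0},
        attraction={(TH, APC): AttractionRule(10.0, 1.0)},
    )
    core = sample_clustered_core(params, 300.0, seed=5)
    assert (core.cells.phenotype == TH).sum() > 0
    assert (core.cells.phenotype == APC).sum() == 0


def test_stratification_recovers_latent_strata():
    """Two-Gaussian HLA-DR overlap (25 vs 8, sd 5): mean-split stratification
    recovers >=80% of latent labels at n=100."""
    cfg = default_config(seed=11, n_patients=100, cores_per_patient=1)
    high = cfg.params["HIGH"]
    low = cfg.params["LOW"]
    cfg = SyntheticConfig(
        n_patients=100, cores_per_patient=1, seed=11,
        params={
            "HIGH": StratumParams(
                densities=high.densities, attraction=high.attraction,
                state_rates=high.state_rates, hladr_mean=25.0, hladr_sd=5.0,
            ),
            "LOW": StratumParams(
                densities=low.densities, attraction=low.attraction,
                state_rates=low.state_rates, hladr_mean=8.0, hladr_sd=5.0,
            ),
        },
    )
    patients, truth = generate_cohort(cfg)
    stratify_cohort_by_mean(patients)
    latent = dict(zip(truth["patient_id"], truth["latent_stratum"]))
    agree = sum(p.stratum.value == latent[p.patient_id] for p in patients)
    assert agree / len(patients) >= 0.80


def test_config_yaml_round_trip(tmp_path):
    cfg = default_config(seed=9, n_patients=5)
    path = tmp_path / "config.yaml"
    cfg.to_yaml(path)
    back = SyntheticConfig.from_yaml(path)
    assert back == cfg


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SyntheticConfig(n_patients=0, params=default_config().params)
    with pytest.raises(ValueError):
        default_config(stratum_fraction_high=1.5)
    with pytest.raises(ValueError):
        StratumParams(densities={"TCELL_CTL": -1e-4})
    with pytest.raises(ValueError):
        AttractionRule(sigma=10.0, fraction_clustered=1.2)
    with pytest.raises(ValueError):
        StratumParams(densities={}, state_rates={("TCELL_CTL", "CD3"): 0.5})


def test_null_config_strata_identical():
    cfg = null_config(seed=1)
    assert cfg.params["HIGH"] == cfg.params["LOW"]
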