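import pandas as pd
import pytest

from prucapop import PKParameters, default_population
from prucapop.cohort_simulator import (ExclusionArtifacts, generate_cohort,
                                       inject_exclusion_artifacts, rich_design,
                                       simulate_trial, sparse_design)
from prucapop.dataset import PKDataset
from prucapop.population import STUDY_RICH, STUDY_SPARSE, PopulationModel


@pytest.fixture(scope="session")
def typical_params() -> PKParameters:
    """Final-model typical parameters at the 70 kg reference size."""
    return PKParameters(cl=20.1, v2=446.0, q=16.9, v3=248.0,
                        ka1=0.792, ka2=3.87, mtime=0.734, f1=0.858)


@pytest.fixture(scope="session")
def pop() -> PopulationModel:
    return default_population()


@pytest.fixture(scope="session")
def quiet_population() -> PopulationModel:
    """Low-variability population used to build deterministic count fixtures
    (no concentration falls below either assay limit)."""
    return default_population().with_updates(
        omega_cl_by_study={STUDY_RICH: 0.1, STUDY_SPARSE: 0.1},
        omega_v2=0.1, omega_v3=0.1,
        sigma_by_study={STUDY_RICH: 0.05, STUDY_SPARSE: 0.05},
    )


@pytest.fixture(scope="session")
def rich_count_fixture(quiet_population) -> PKDataset:
    """38 subjects × 13 scheduled samples with 13 rows flagged for exclusion
    (7 forced below the quantification limit, 6 with missing sample times)."""
    design = rich_design(38)
    cohort = generate_cohort(design, seed=101)
    ds = simulate_trial(cohort, design, quiet_population, seed=102,
                        apply_artifacts=False)
    assert len(ds.observations) == 494
    n_natural_bql = int(ds.observations["BQL"].sum())
    assert n_natural_bql <= 7
    return inject_exclusion_artifacts(
        ds, ExclusionArtifacts(bql=7 - n_natural_bql, missing_time=6),
        lloq=design.lloq_ng_ml, seed=103)


@pytest.fixture(scope="session")
def sparse_count_fixture(quiet_population) -> PKDataset:
    """107 subjects with 291 collected samples; 25 below-limit rows, one
    not-analyzed row, and 21 missing-dose rows arranged so one subject loses
    every record (244 retained from 106 subjects)."""
    design = sparse_design(107)
    cohort = generate_cohort(design, seed=201)
    ds = simulate_trial(cohort, design, quiet_population, seed=202,
                        apply_artifacts=False)
    assert len(ds.observations) == 321
    assert int(ds.observations["BQL"].sum()) == 0
    ds = inject_exclusion_artifacts(
        ds, ExclusionArtifacts(bql=25, missing_dose_info=21, missing_obs=1,
                               uncollected=30, exclude_one_subject=True),
        lloq=design.lloq_ng_ml, seed=203)
    obs = ds.observations
    assert len(obs) == 291
    # every subject still has at least one collected sample
    assert obs["ID"].nunique() == 107
    return ds


def make_joint_dataset(seed: int, pop: PopulationModel | None = None,
                       n_rich: int = 38, n_sparse: int = 107) -> PKDataset:
    """Simulate, clean, and join both study arms (the recovery experiment)."""
    from prucapop.data_prep import filter_records

    pop = pop or default_population()
    rd, sd = rich_design(n_rich), sparse_design(n_sparse)
    ds_r = simulate_trial(generate_cohort(rd, seed=seed * 1000 + 1), rd, pop,
                          seed=seed * 1000 + 2)
    ds_s = simulate_trial(generate_cohort(sd, seed=seed * 1000 + 3), sd, pop,
                          seed=seed * 1000 + 4)
    clean_r, _ = filter_records(ds_r, lloq=rd.lloq_ng_ml)
    clean_s, _ = filter_records(ds_s, lloq=sd.lloq_ng_ml)
    return PKDataset(pd.concat([clean_r.records, clean_s.records],
                               ignore_index=True))
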