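import numpy as np
import pandas as pd
import pytest

from melsyn.containers import ExpressionExperiment
from melsyn.grouping import GroupAssignment
from melsyn.pipeline import PipelineConfig, StageParams, run_pipeline
from melsyn.synthetic import default_truth, generate_bundle

#: one fixed seed for the session-scoped synthetic study
SESSION_SEED = 11


@pytest.fixture(scope="session")
def truth():
    return default_truth()


@pytest.fixture(scope="session")
def bundle(truth):
    return generate_bundle(seed=SESSION_SEED, truth=truth)


@pytest.fixture(scope="session")
def planted_assignment(truth):
    """Group assignment read directly off the planted truth."""
    return GroupAssignment(groups=pd.Series(truth.true_groups))


@pytest.fixture(scope="session")
def report():
    """Full default-synthetic pipeline run (bootstrap kept small for speed)."""
    cfg = PipelineConfig(seed=SESSION_SEED, synthetic={}, params=StageParams(n_bootstrap=50))
    return run_pipeline(cfg)


@pytest.fixture(scope="session")
def recovered_label_of(report):
    """Map a planted group name to its label in the recovered clustering.

    Recovered groups are named by dendrogram leaf order, so labels are a
    permutation of the planted names whenever the partition is recovered.
    """
    truth = report.truth
    rec = report.groups.groups

    def _map(planted_group: str) -> str:
        members = [ln for ln, g in truth.true_groups.items() if g == planted_group]
        labels = set(rec[members])
        assert len(labels) == 1, f"planted group {planted_group} split across {labels}"
        return labels.pop()

    return _map


def make_expression(values: dict[str, list[float]], meta: list[tuple[str, str, int]], features=None):
    """Small helper for hand-built expression fixtures.

    ``values`` maps sample id -> per-feature values; ``meta`` lists
    (line, treatment, replicate) in the same sample order.
    """
    samples = list(values)
    mat = pd.DataFrame(values)
    if features is not None:
        mat.index = features
    sm = pd.DataFrame(meta, columns=["line", "treatment", "replicate"], index=samples)
    return ExpressionExperiment(values=mat, samples=sm)


def make_null_paired_experiment(n_features: int, seed: int, n_lines: int = 4):
    """Null paired design: ``n_lines`` x 2 replicates, no treatment effect."""
    gen = np.random.default_rng(seed)
    lines = [f"L{i}" for i in range(n_lines)]
    values, meta = {}, []
    for line in lines:
        for trt in ("control", "treated"):
            for rep in (1, 2):
                values[f"{line}_{trt}_{rep}"] = gen.normal(0, 1, n_features)
                meta.append((line, trt, rep))
    mat = pd.DataFrame(values, index=[f"f{i}" for i in range(n_features)])
    samples = pd.DataFrame(meta, columns=["line", "treatment", "replicate"], index=mat.columns)
    groups = GroupAssignment(groups=pd.Series({ln: "G" for ln in lines}))
    return ExpressionExperiment(values=mat, samples=samples), groups


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
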