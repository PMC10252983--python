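import numpy as np
import pytest

from skintex.ablation import STANDARD_SEEDS, desk_configs, standard_fixture
from skintex.synthetic import SceneSpec, generate_scene
from skintex.train import TrainConfig, run_ablation


@pytest.fixture(scope="session")
def sample96():
    """One default synthetic sample (96x96, 5 wrinkles, 25 pores, 10
    distractors)."""
    return generate_scene(SceneSpec(seed=7))


@pytest.fixture(scope="session")
def study():
    """The standard multi-seed ablation study: four model rows trained per
    seed on the desk-scale synthetic fixture. Shared across tests because
    training dominates suite runtime."""
    results = []
    for seed in STANDARD_SEEDS:
        train_samples, val_samples = standard_fixture(seed)
        rows = run_ablation(
            desk_configs(), train_samples, val_samples,
            TrainConfig(seed=seed), keep_models=True,
        )
        results.append(
            {"seed": seed, "rows": rows, "train": train_samples, "val": val_samples}
        )
    return results


def median_metric(results, name: str, key: str) -> float:
    rows = [
        r for res in results for r in res["rows"] if r["name"] == name
    ]
    return float(np.median([r[key] for r in rows]))
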