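import pytest

import knockscan as ks


@pytest.fixture
def toy1():
    return ks.make_toy1()


@pytest.fixture
def toy1_json(toy1, tmp_path):
    path = tmp_path / "toy1.json"
    ks.save_model(toy1, path)
    return path


@pytest.fixture
def grnt_config():
    return ks.TraversalConfig(target_level=2, mode="rate_grnt")


def toy_and_removable(seed, n_branches=3, gpr_style="one-to-one"):
    """Seeded toy plus its preprocessed candidate set (shared test helper)."""
    model = ks.generate_toy_model(
        ks.ToyModelSpec(seed=seed, n_branches=n_branches, gpr_style=gpr_style)
    )
    report = ks.compute_removable_set(model)
    return model, report.removable
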