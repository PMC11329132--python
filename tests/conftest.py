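import numpy as np
import pytest

import ctthinslice as ct


@pytest.fixture(scope="session")
def small_case() -> ct.PairedCase:
    """A 9-slice, 32x32 paired phantom case (3 thick slices at k=3)."""
    cfg = ct.PhantomConfig(shape=(9, 32, 32), seed=7)
    return ct.make_paired_case(cfg, k=3, case_id="small")


@pytest.fixture(scope="session")
def medium_case() -> ct.PairedCase:
    """A 30-slice, 64x64 paired case matching the default study shape."""
    cfg = ct.PhantomConfig(shape=(30, 64, 64), seed=11)
    return ct.make_paired_case(cfg, k=3, case_id="medium")


@pytest.fixture(scope="session")
def constant_case() -> ct.PairedCase:
    """Thin = thick everywhere: three identical constant slices."""
    thin = ct.CTVolume(np.full((3, 32, 32), 1000, dtype=np.uint16), 1.0, 1.0)
    thick = ct.degrade_to_thick(thin, 3)
    return ct.PairedCase(thin=thin, thick=thick,
                         mapping=ct.build_mapping(3, 3), case_id="const")


@pytest.fixture(scope="session")
def tiny_train_config() -> ct.TrainingConfig:
    """A seconds-scale training profile for mechanics-level tests."""
    return ct.TrainingConfig(epochs=2, gen_depth=4, gen_width=8,
                             disc_blocks=2, disc_width=8, seed=3)


@pytest.fixture(scope="session")
def tiny_cases() -> list[ct.PairedCase]:
    """Three small cases for fast cross-validation bookkeeping tests."""
    return ct.phantom_suite(3, base_seed=40, shape=(9, 16, 16))
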