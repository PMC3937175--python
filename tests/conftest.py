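from types import SimpleNamespace

import pytest
from hypothesis import HealthCheck, settings

import primebias as pb

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def deep_sim():
    """One deep simulated study, shared across tests.

    Uniform synthetic library of 2e6 inserts, amplified twice (independent
    seeds, 2e6 reads each) under the default GC-favoring factorized
    preference model — the conditions used for replicate-correlation and
    parameter-recovery checks.
    """
    model = pb.PreferenceModel.gc_favoring(1.3)
    sl = pb.simulate_inserts(2_000_000, seed=20240101)
    amp1 = pb.simulate_amplified_inserts(sl, model, 2_000_000, seed=20240102)
    amp2 = pb.simulate_amplified_inserts(sl, model, 2_000_000, seed=20240103)
    w6, w8 = pb.WINDOWS["w6"], pb.WINDOWS["w8"]
    bg6, bg8 = pb.count_windows(sl, w6), pb.count_windows(sl, w8)
    return SimpleNamespace(
        model=model,
        sl=sl,
        amp1=amp1,
        amp2=amp2,
        bg6=bg6,
        bg8=bg8,
        obv6_rep1=pb.compute_obv(pb.count_windows(amp1, w6), bg6),
        obv6_rep2=pb.compute_obv(pb.count_windows(amp2, w6), bg6),
        obv8_rep1=pb.compute_obv(pb.count_windows(amp1, w8), bg8),
    )


@pytest.fixture()
def design():
    return pb.LibraryDesign()


@pytest.fixture()
def barcode_table():
    return pb.BarcodeTable((
        ("SL", "AAGG", "unamplified background"),
        ("amp1", "CCTT", "amplified replicate 1"),
    ))
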