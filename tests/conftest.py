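import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from vocalseq.types import AcousticMeasures, MimeticSequence, UnitClass

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def mk_seq(bird, pop, codes, classes=None, acoustics=None, position=0):
    """Build a MimeticSequence with mimetic-vocal classes by default."""
    if classes is None:
        classes = [UnitClass.MIMETIC_VOCAL] * len(codes)
    return MimeticSequence(
        bird_id=bird,
        population_id=pop,
        codes=tuple(codes),
        unit_classes=tuple(classes),
        acoustics=acoustics,
        position=position,
    )


def mk_acoustics(peak=3.0, low=2.0, high=4.0, dur=0.5, ent=4.0, power=60.0):
    return AcousticMeasures(
        peak_frequency=peak,
        low_frequency_5pct=low,
        high_frequency_95pct=high,
        bandwidth_90pct=high - low,
        duration_90pct=dur,
        aggregate_entropy=ent,
        peak_power=power,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """Structured 3-population dataset whose sharing decays with level."""
    import vocalseq as vs

    cfg = vs.SyntheticConfig(
        n_populations=3,
        birds_per_population=3,
        sequences_per_bird_mean=6,
        sequences_per_bird_sd=1,
        alphabet_size_range=(10, 14),
        global_pool_size=30,
        template_length_mean=10,
        template_length_sd=2,
        template_length_bounds=(4, 20),
    )
    return vs.generate_dataset(cfg, seed=11)


@pytest.fixture(scope="session")
def small_sequences(small_dataset):
    import vocalseq as vs

    seqs, _ = vs.segment_dataset(small_dataset.bouts_by_bird)
    return seqs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
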