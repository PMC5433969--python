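import datetime as dt

import numpy as np
import pytest

from cetcond.records import MorphRecord
from cetcond.simulate import SynthConfig


@pytest.fixture
def default_config() -> SynthConfig:
    return SynthConfig(seed=1)


def make_record(i=0, mass=33.1, length=135.0, **kw) -> MorphRecord:
    base = dict(
        id=f"r{i}",
        sex="male",
        date=dt.date(2015, 7, 1),
        cod_class="acute",
        mass=mass,
        length=length,
        girth=70.0,
        blubber_dorsal=13.0,
        blubber_lateral=12.0,
        blubber_ventral=14.0,
    )
    base.update(kw)
    return MorphRecord(**base)


@pytest.fixture
def power_law_records():
    """Records exactly on mass = a * length**b with a=e^-9, b=2."""
    rng = np.random.default_rng(0)
    lengths = rng.uniform(80, 160, size=25)
    mass = np.exp(2.0 * np.log(lengths) - 9.0)
    return [make_record(i, mass=m, length=ln) for i, (m, ln) in enumerate(zip(mass, lengths))]
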