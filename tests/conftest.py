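import math

import numpy as np
import pytest

from mmrscreen import blot_synth as bs
from mmrscreen import densitometry as ds


@pytest.fixture
def noiseless_blot() -> bs.BlotConfig:
    return bs.BlotConfig(noise_sd=0.0)


@pytest.fixture
def default_blot() -> bs.BlotConfig:
    return bs.BlotConfig()


@pytest.fixture
def stim() -> bs.StimulationParams:
    return bs.StimulationParams()


@pytest.fixture
def cell_line_subject() -> bs.SubjectSpec:
    return bs.SubjectSpec(subject_id="SW480", cell_type=bs.CellType.CELL_LINE)


def gaussian_area(amplitude: float, sigma: float, window: tuple[int, int], mu: float) -> float:
    """Independent oracle: closed-form area of an amplitude-A Gaussian
    band restricted to a half-open pixel window.

    The discrete intensity sum over integer pixels [start, end) is the
    midpoint-rule approximation of the integral over
    [start - 0.5, end - 0.5], so the erf coverage uses those limits.
    """
    start, end = window
    s2 = sigma * math.sqrt(2.0)
    coverage = 0.5 * (
        math.erf((end - 0.5 - mu) / s2) - math.erf((start - 0.5 - mu) / s2)
    )
    return amplitude * sigma * math.sqrt(2.0 * math.pi) * coverage


@pytest.fixture
def fig1a_lanes(stim) -> list[tuple[bs.SubjectSpec, bs.StimulationParams]]:
    """SW480 (both bands), HCT116 (MSH2 only), LoVo (MLH1 only)."""
    mk = lambda sid, mlh1, msh2: bs.SubjectSpec(
        subject_id=sid,
        cell_type=bs.CellType.CELL_LINE,
        base_abundance_mlh1=mlh1,
        base_abundance_msh2=msh2,
    )
    return [
        (mk("SW480", 1.0, 1.0), stim),
        (mk("HCT116", 0.0, 1.0), stim),
        (mk("LoVo", 1.0, 0.0), stim),
    ]
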