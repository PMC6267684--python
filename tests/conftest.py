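import numpy as np
import pytest

from ncakit.profiles import (
    METARRESTIN,
    ConcentrationRecord,
    ConcentrationTimeProfile,
    DoseRegimen,
)


def make_profile(
    times,
    concs,
    route="IV",
    dose=3.0,
    matrix="plasma",
    n_doses=1,
    arm_id="test",
    blq=None,
):
    """Build a validated profile from parallel time/concentration arrays.

    ``concs[i] = None`` (or ``blq[i] = True``) marks a BLQ record.
    """
    blq = [False] * len(times) if blq is None else blq
    records = tuple(
        ConcentrationRecord(
            time=float(t),
            concentration=None if (b or c is None) else float(c),
            blq=bool(b or c is None),
            n_animals=3,
        )
        for t, c, b in zip(times, concs, blq)
    )
    return ConcentrationTimeProfile(
        arm_id=arm_id,
        matrix=matrix,
        regimen=DoseRegimen(route=route, dose_level=dose, n_doses=n_doses),
        analyte=METARRESTIN,
        records=records,
    )


@pytest.fixture
def monoexp_profile():
    """Exactly monoexponential IV decay, C(t) = 100·e^(−0.1 t)."""
    t = np.array([10.0, 15.0, 20.0, 24.0])
    return make_profile(t, 100.0 * np.exp(-0.1 * t))
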