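import numpy as np
import pytest

from graftcalib import Cohort, DonorRecord, MethodVolumes


@pytest.fixture
def small_cohort() -> Cohort:
    """Three hand-written donors, two methods, totals and recipients present."""
    def rec(i, agw, auto, auto_t, manu, manu_t, recip):
        return DonorRecord(
            donor_id=f"D{i}",
            agw=agw,
            volumes={
                "automated": MethodVolumes(auto, auto_t),
                "manual": MethodVolumes(manu, manu_t),
            },
            recipient_weight=recip,
            covariates={"age": 30.0 + i, "sex": "M", "bmi": 24.5,
                        "op_method": "open"},
        )

    records = [
        rec(1, 780.0, 860.5, 1360.25, 871.125, 1320.0, 63.0),
        rec(2, 650.0, 731.0, 1150.0, 741.5, 1115.75, 55.5),
        rec(3, 905.25, 1001.0, 1580.5, 1012.375, 1530.0, 71.25),
    ]
    return Cohort(records=records, methods=["automated", "manual"])


@pytest.fixture
def paired_data():
    """Correlated (egv, agw) arrays for agreement statistics."""
    rng = np.random.default_rng(42)
    agw = rng.lognormal(6.64, 0.21, 80)
    egv = agw / 0.85 * np.exp(rng.normal(0, 0.12, 80))
    return egv, agw
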