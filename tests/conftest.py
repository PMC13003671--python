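import datetime as dt

import pytest

from gardenset.sheets import ObservationRecord, ObservationSeries


def make_series(
    O,
    F,
    R,
    H,
    plant_id="P1",
    garden_id="G1",
    year=2021,
    crop="cucumber",
    dates=None,
    comments=None,
    interval_days=3,
):
    """Build an observation series from parallel count vectors."""
    n = len(O)
    assert len(F) == len(R) == len(H) == n
    base = dt.date(2021, 6, 1)
    if dates is None:
        dates = [base + dt.timedelta(days=interval_days * i) for i in range(n)]
    comments = comments or {}
    records = [
        ObservationRecord(
            visit_date=dates[i],
            open_flowers=O[i],
            faded_flowers=F[i],
            fruits_on_plant=R[i],
            fruits_harvested=H[i],
            comment=comments.get(i),
        )
        for i in range(n)
    ]
    return ObservationSeries(
        plant_id=plant_id,
        garden_id=garden_id,
        year=year,
        crop=crop,
        crop_raw=crop,
        records=records,
    )


@pytest.fixture
def worked_series():
    """The five-visit series whose ledger is worked through by hand.

    O=(2,3,1,0,0), F=(0,1,2,1,0), R=(0,0,2,2,1), H=(0,0,0,1,1):
    unit totals U=(2,4,5,4,3), new units n=(2,2,1,0,0), no last-visit
    subtraction -> 5 flowers; new fruits (0,0,2,1,0) -> 3 fruits; 60%.
    """
    return make_series(
        O=(2, 3, 1, 0, 0),
        F=(0, 1, 2, 1, 0),
        R=(0, 0, 2, 2, 1),
        H=(0, 0, 0, 1, 1),
    )
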