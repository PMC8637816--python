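import io

import pytest

from liplead import (
    Category,
    ExposureParams,
    SamplePanel,
    SampleRecord,
    fit_from_summary,
)

PANEL_CSV = """\
sample_id,category,brand,production_country,color,price_rmb,pb_mg_per_kg
LS1,lipstick,Brand A,Country 1,true red,320,0.13849
LS2,Lipstick,Brand B,Country 2,orange,158,0
LG1,lip_gloss,Brand C,Country 1,pink,90,0.02
"""


@pytest.fixture
def panel_csv():
    return io.StringIO(PANEL_CSV)


def make_record(sample_id="S1", category=Category.LIPSTICK, pb=0.1, **kw):
    defaults = dict(
        brand="Brand A",
        production_country="Country 1",
        color="red",
        price_rmb=100.0,
        detected=pb > 0,
    )
    defaults.update(kw)
    return SampleRecord(sample_id=sample_id, category=category,
                        pb_mg_per_kg=pb, **defaults)


def make_panel(values, category=Category.LIPSTICK):
    return SamplePanel(tuple(
        make_record(sample_id=f"S{i}", category=category, pb=v)
        for i, v in enumerate(values)
    ))


@pytest.fixture
def small_panel():
    return make_panel([0.1, 0.2, 0.3])


@pytest.fixture
def average_user():
    return ExposureParams.average_user()


@pytest.fixture
def high_user():
    return ExposureParams.high_user()


@pytest.fixture
def paper_like_fit():
    """Lognormal moment-matched to the study's overall mean 0.05791 / sd 0.10146."""
    return fit_from_summary(0.05791, 0.10146)
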