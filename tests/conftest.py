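import pytest

from bwsurvey import (
    PreferenceModel,
    ResponseRecord,
    default_catalog,
    generate_design,
)
from bwsurvey.catalog import benefit_task_items, harm_item_ids


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def benefit_ids(catalog):
    return benefit_task_items(catalog)


@pytest.fixture(scope="session")
def harms(catalog):
    return harm_item_ids(catalog)


@pytest.fixture(scope="session")
def design21(catalog, harms):
    """Survey-scale design: 21 harms in 12 blocks of 7, seeded."""
    return generate_design(21, 12, 7, seed=11, item_ids=harms)


@pytest.fixture(scope="session")
def flat_model(catalog):
    return PreferenceModel.for_catalog(catalog)


def make_complete_record(rid, benefit_ids, set_items, set_id, **kwargs):
    """A fully-complete respondent with identity rankings by list order."""
    defaults = dict(
        birth_year=1970,
        birth_month=set_id,
        gender="female",
        has_tmj_condition=True,
        ppi=4,
        comorbid_pain_count=2,
        current_med_count=1,
        past_med_count=3,
        benefit_ranks={item: i + 1 for i, item in enumerate(benefit_ids)},
        harm_set_id=set_id,
        harm_ranks={item: i + 1 for i, item in enumerate(set_items)},
        tradeoff="benefits",
    )
    defaults.update(kwargs)
    return ResponseRecord(respondent_id=rid, **defaults)


@pytest.fixture
def six_row_fixture(benefit_ids, design21):
    """Hand-built cascade fixture: 1 non-TMJ, 1 missing PPI, 1 incomplete
    benefits only, 1 incomplete harms only, 2 fully complete."""
    set_items = design21.block_items(1)
    partial_benefits = {item: i + 1 for i, item in enumerate(benefit_ids[:-1])}
    partial_harms = {item: i + 1 for i, item in enumerate(set_items[:-1])}
    return [
        make_complete_record("non_tmj", benefit_ids, set_items, 1,
                             has_tmj_condition=False),
        make_complete_record("no_ppi", benefit_ids, set_items, 1, ppi=None),
        make_complete_record("partial_benefit", benefit_ids, set_items, 1,
                             benefit_ranks=partial_benefits),
        make_complete_record("partial_harm", benefit_ids, set_items, 1,
                             harm_ranks=partial_harms),
        make_complete_record("ok1", benefit_ids, set_items, 1),
        make_complete_record("ok2", benefit_ids, set_items, 1),
    ]
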