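"""ATC catalog lookups and anticholinergic burden counting."""

import logging

import pytest

from pimscreen.drugs import anticholinergic_burden, classify, load_catalog
from pimscreen.recipes import med

#: All twenty ATC codes of the published top-drug attribution table.
TOP20_CODES = [
    "A10BB12", "A10BG03", "B01AA03", "B01AB05", "B01AC04", "B01AC06",
    "C01AA05", "C01DA02", "C02DB02", "C03CA01", "C07AB03", "C07AB07",
    "C07AG02", "D04AA16", "H02AB09", "M01AB05", "N02AX02", "N03AE01",
    "N04AA04", "N05AX08",
]


def test_aspirin_classified_as_antiplatelet():
    tags = classify("B01AC06")
    assert {"aspirin", "antiplatelet"} <= tags


def test_pheniramine_is_first_generation_antihistamine():
    assert "first_gen_antihistamine" in classify("D04AA16")


def test_every_top20_code_resolves_to_tags():
    for code in TOP20_CODES:
        assert classify(code), f"{code} resolved to no tags"


def test_unknown_but_valid_code_returns_empty_with_warning(caplog):
    with caplog.at_level(logging.WARNING, logger="pimscreen.drugs"):
        assert classify("Z99ZZ99") == frozenset()
    assert any("Z99ZZ99" in r.message for r in caplog.records)


def test_malformed_code_raises():
    with pytest.raises(ValueError, match="malformed"):
        classify("aspirin")


def test_classify_is_deterministic_pure_lookup():
    assert classify("C07AG02") == classify("C07AG02")
    catalog = load_catalog()
    assert catalog is load_catalog()  # cached, no re-read


class TestAnticholinergicBurden:
    def test_empty_list(self):
        assert anticholinergic_burden([]) == 0

    def test_two_regular_antimuscarinics(self):
        meds = [med("D04AA16", 25), med("N06AA09", 25)]
        assert anticholinergic_burden(meds) == 2

    def test_prn_orders_excluded(self):
        assert anticholinergic_burden([med("D04AA16", 25, prn=True)]) == 0

    def test_duplicate_codes_count_once(self):
        meds = [med("D04AA16", 25), med("D04AA16", 50)]
        assert anticholinergic_burden(meds) == 1

    def test_non_anticholinergics_ignored(self):
        assert anticholinergic_burden([med("N02BE01", 500), med("C07AB03", 50)]) == 0
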