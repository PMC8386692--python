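from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

from kflc import Diagnosis, count_fixture, kappa_index, ocb_positive

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_cohort():
    """The deterministic 252-patient count-fixture cohort."""
    return count_fixture()


def marginal_counts(cohort) -> dict[str, int]:
    """Joint/marginal counts of a cohort over diagnosis, censoring, OCB
    status and K-Index cutoff strata (used to pin the count fixture to
    every published figure)."""
    rows = []
    for r in cohort:
        res = kappa_index(r)
        rows.append(
            {
                "diag": r.diagnosis,
                "cens": not res.csf_detectable,
                "ocb": ocb_positive(r.ocb_bands) if r.ocb_tested else None,
                "k": res.k_index,
            }
        )

    def count(pred):
        return sum(1 for x in rows if pred(x))

    d = Diagnosis
    return {
        "n": len(rows),
        "n_ms": count(lambda x: x["diag"] is d.MS),
        "n_cis": count(lambda x: x["diag"] is d.CIS),
        "n_ris": count(lambda x: x["diag"] is d.RIS),
        "n_inconclusive": count(lambda x: x["diag"] is d.INCONCLUSIVE),
        "n_other": count(lambda x: x["diag"] is d.OTHER),
        "censored": count(lambda x: x["cens"]),
        "censored_other": count(lambda x: x["cens"] and x["diag"] is d.OTHER),
        "censored_inconclusive": count(
            lambda x: x["cens"] and x["diag"] is d.INCONCLUSIVE
        ),
        "censored_ms": count(lambda x: x["cens"] and x["diag"] is d.MS),
        "detectable": count(lambda x: not x["cens"]),
        "detectable_ocb_pos": count(lambda x: not x["cens"] and x["ocb"]),
        "detectable_ocb_neg": count(lambda x: not x["cens"] and x["ocb"] is False),
        "ocb_pos": count(lambda x: x["ocb"]),
        "ocb_pos_ms": count(lambda x: x["ocb"] and x["diag"] is d.MS),
        "ocb_pos_ris": count(lambda x: x["ocb"] and x["diag"] is d.RIS),
        "ocb_pos_cis": count(lambda x: x["ocb"] and x["diag"] is d.CIS),
        "ocb_pos_inconclusive": count(
            lambda x: x["ocb"] and x["diag"] is d.INCONCLUSIVE
        ),
        "ocb_pos_other": count(lambda x: x["ocb"] and x["diag"] is d.OTHER),
        "ocb_pos_censored": count(lambda x: x["ocb"] and x["cens"]),
        "ocb_pos_censored_ms": count(
            lambda x: x["ocb"] and x["cens"] and x["diag"] is d.MS
        ),
        "ocb_pos_other_detectable": count(
            lambda x: x["ocb"] and not x["cens"] and x["diag"] is d.OTHER
        ),
        "ocb_neg_ms": count(lambda x: x["ocb"] is False and x["diag"] is d.MS),
        "ocb_neg_other": count(lambda x: x["ocb"] is False and x["diag"] is d.OTHER),
        "ms_gt_3045": count(lambda x: x["diag"] is d.MS and x["k"] > 3.045),
        "ms_gt_66": count(lambda x: x["diag"] is d.MS and x["k"] > 6.6),
        "ms_gt_1258": count(lambda x: x["diag"] is d.MS and x["k"] > 12.58),
        "other_gt_3045": count(lambda x: x["diag"] is d.OTHER and x["k"] > 3.045),
        "other_gt_66": count(lambda x: x["diag"] is d.OTHER and x["k"] > 6.6),
        "other_gt_1258": count(lambda x: x["diag"] is d.OTHER and x["k"] > 12.58),
        "detectable_le_3045": count(lambda x: not x["cens"] and x["k"] <= 3.045),
        "ocb_pos_gt_3045": count(lambda x: x["ocb"] and x["k"] > 3.045),
        "ocb_pos_gt_66": count(lambda x: x["ocb"] and x["k"] > 6.6),
        "ocb_pos_gt_1258": count(lambda x: x["ocb"] and x["k"] > 12.58),
    }


#: Published counts the fixture must satisfy simultaneously.
EXPECTED_MARGINALS = {
    "n": 252,
    "n_ms": 45,
    "n_cis": 1,
    "n_ris": 2,
    "n_inconclusive": 7,
    "n_other": 197,
    "censored": 160,
    "censored_other": 157,
    "censored_inconclusive": 2,
    "censored_ms": 1,
    "detectable": 92,
    "detectable_ocb_pos": 62,
    "detectable_ocb_neg": 30,
    "ocb_pos": 65,
    "ocb_pos_ms": 40,
    "ocb_pos_ris": 2,
    "ocb_pos_cis": 1,
    "ocb_pos_inconclusive": 4,
    "ocb_pos_other": 18,
    "ocb_pos_censored": 3,
    "ocb_pos_censored_ms": 0,
    "ocb_pos_other_detectable": 15,
    "ocb_neg_ms": 5,
    "ocb_neg_other": 179,
    "ms_gt_3045": 44,
    "ms_gt_66": 42,
    "ms_gt_1258": 41,
    "other_gt_3045": 27,
    "other_gt_66": 25,
    "other_gt_1258": 19,
    "detectable_le_3045": 13,
    "ocb_pos_gt_3045": 61,
    "ocb_pos_gt_66": 59,
    "ocb_pos_gt_1258": 58,
}
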