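import math

import pytest

from pafkit.cohort import SubjectRecord, TriBool
from pafkit.simulate import default_study_config, simulate_cohort


def make_binary_records(a, b, c, d, exposure="pesticide", sex=None, start=0):
    """Expand a 2x2 table into subject records for one binary exposure.

    a/b exposed/unexposed cases, c/d exposed/unexposed controls; all other
    fields stay unknown so complete-case filtering touches only the
    exposure.
    """
    records = []
    i = start
    for status, exposed, count in [("case", True, a), ("case", False, b),
                                   ("control", True, c), ("control", False, d)]:
        for _ in range(count):
            i += 1
            kwargs = {"subject_id": f"X{i:06d}", "status": status}
            if sex is not None:
                kwargs["sex"] = sex
            if exposure == "family_history":
                kwargs["family_history"] = "positive" if exposed else "negative"
            else:
                kwargs[exposure] = TriBool.YES if exposed else TriBool.NO
            records.append(SubjectRecord(**kwargs).validate())
    return records


@pytest.fixture(scope="session")
def study_cohort():
    """One study-scale synthetic cohort (808 cases / 415 controls)."""
    return simulate_cohort(default_study_config(seed=2))
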