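"""Reference cohort table of the DEFA6/NEC study population.

Twelve infants who underwent bowel resection (eight with necrotizing
enterocolitis, four dysmotility controls), with gestational age at birth
and at surgery in the conventional weeks+days notation.  The table serves
as a worked example for the gestational-age arithmetic and as the schema
template for simulated cohorts.
"""

from __future__ import annotations

import io

import pandas as pd

from .cohort import CohortRecord, GestationalAge

__all__ = ["load_study_cohort", "study_cohort_records"]

_STUDY_COHORT_CSV = """\
patient_id,diagnosis,group,tissue,ga_birth,birth_weight_g,ga_surgery,postnatal_age_days,sex
12244-04_B1,NEC,NEC,ileum,27+6,1438,28+4,5,M
9589-10_B,NEC,NEC,ileum,23+2,585,30+3,50,M
12106-10_C,NEC,NEC,ileum,26+2,1025,27+1,6,M
18596-11_L,NEC,NEC,colon,39+0,2360,39+4,4,M
23543-11_B,NEC,NEC,ileum,29+2,1225,29+6,4,M
6126-12_A,NEC,NEC,jejunum,26+2,912,31+0,33,M
6436-13_C,NEC,NEC,ileum,24+1,597,25+6,12,F
33-04_B,NEC,NEC,ileum,34+3,2300,35+2,6,F
13749-07_A,dysmotility,control,ileum,36+4,3075,39+6,23,M
3267-13,dysmotility,control,ileum,25+6,622,31+1,37,F
315-10_1,dysmotility,control,ileum,40+4,4320,41+1,4,F
873-12_5,dysmotility,control,ileum,25+0,870,31+5,47,F
"""


def load_study_cohort() -> pd.DataFrame:
    """The study population table as a DataFrame.

    ``ga_birth`` and ``ga_surgery`` are kept as weeks+days strings;
    ``group`` is derived from the diagnosis (NEC vs dysmotility control).
    """
    return pd.read_csv(io.StringIO(_STUDY_COHORT_CSV))


def study_cohort_records() -> list[CohortRecord]:
    """The same table as typed :class:`~dabquant.cohort.CohortRecord` objects."""
    df = load_study_cohort()
    return [
        CohortRecord(
            patient_id=row.patient_id,
            group=row.group,
            tissue=row.tissue,
            ga_birth=GestationalAge.from_string(row.ga_birth),
            birth_weight_g=float(row.birth_weight_g),
            postnatal_age_days=int(row.postnatal_age_days),
            sex=row.sex,
        )
        for row in df.itertuples()
    ]
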