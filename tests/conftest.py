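import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from divigil.faers_io import QuarterBundle, link_cases
from divigil.resources import load_atc_map, load_synonym_map


@pytest.fixture(scope="session")
def synonym_map():
    return load_synonym_map()


@pytest.fixture(scope="session")
def atc_map():
    return load_atc_map()


def make_bundle(demo_rows, drug_rows=(), reac_rows=(), ther_rows=(), outc_rows=()):
    """Build a QuarterBundle from terse row tuples.

    demo: (primaryid, caseid, fda_dt, event_dt, age, age_cod, sex, wt, occp, country)
    drug: (primaryid, caseid, drug_seq, role_cod, drugname, start_dt)
    reac: (primaryid, caseid, pt, pt_cod)
    ther: (primaryid, caseid, dsg_drug_seq, start_dt)
    outc: (primaryid, caseid, outc_cod)
    """
    def df(rows, cols):
        return pd.DataFrame([list(map(str, r)) for r in rows], columns=cols, dtype=str) \
            if rows else pd.DataFrame({c: pd.Series(dtype=str) for c in cols})

    return QuarterBundle(
        demo=df(demo_rows, ["primaryid", "caseid", "fda_dt", "event_dt", "age",
                            "age_cod", "sex", "wt", "occp_cod", "occr_country"]),
        drug=df(drug_rows, ["primaryid", "caseid", "drug_seq", "role_cod",
                            "drugname", "start_dt"]),
        reac=df(reac_rows, ["primaryid", "caseid", "pt", "pt_cod"]),
        ther=df(ther_rows, ["primaryid", "caseid", "dsg_drug_seq", "start_dt"]),
        outc=df(outc_rows, ["primaryid", "caseid", "outc_cod"]),
    )


def demo_row(primaryid, caseid, fda_dt="20230115", event_dt="20230101", age="47",
             age_cod="YR", sex="F", wt="70", occp="MD", country="US"):
    return (primaryid, caseid, fda_dt, event_dt, age, age_cod, sex, wt, occp, country)


def linked(bundle):
    return link_cases(bundle)
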