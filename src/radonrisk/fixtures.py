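"""Published summary tables, transcribed as checksummed text fixtures.

Two tables ship with the package: the pooled-study sample characteristics
(counts of cases and controls by site, smoking status, sex, and histology)
and the binned exposure table (per-bin case/control counts with the
study's adjusted ORs and the previously published external estimates of
Darby, Krewski and Lubin).  The external OR columns are carried for
side-by-side display only -- nothing in the pipeline fits to them.
"""

from __future__ import annotations

import hashlib
import io

import pandas as pd

__all__ = ["load_fixture_tables", "table1_percentages"]

TABLE1_CSV = """\
section,level,n_controls,n_cases
total,all,5562,8927
site,CAPUA,827,856
site,EAGLE,1983,1873
site,HSPH,1720,4138
site,NICCC-LCA,525,659
site,MSH-PMH,507,1401
smoking,never,1888,889
smoking,former,2495,3984
smoking,current,1179,4054
sex,male,3601,5422
sex,female,1961,3505
histology,AdenoLC,0,4890
histology,SqCLC,0,2210
histology,SCLC,0,730
histology,LCLC,0,408
histology,unknown,0,689
"""

TABLE2_CSV = """\
bin,lo,hi,n_cases,n_controls,mean_sir,or_adj_ref50_75,or_lo,or_hi,darby_or,krewski_or,lubin_or
<25,4,25,83,48,18,0.99,0.65,1.50,0.97,0.95,
25-<50,25,50,1302,1055,42,0.98,0.85,1.12,1.03,1.08,
50-<75,50,75,3171,2195,62,1.00,,,1.00,1.00,1.00
75-<100,75,100,1142,811,88,1.36,1.18,1.56,,1.09,
100-<150,100,150,1912,886,131,1.26,1.11,1.43,1.17,1.16,
150-<200,150,200,1166,491,156,1.21,1.03,1.41,,1.13,1.42
200-<250,200,250,75,30,213,1.81,1.12,2.94,,,1.13
250-<300,250,300,43,31,269,0.78,0.45,1.34,1.15,,1.27
300-<400,300,400,29,14,337,0.87,0.44,1.71,,1.23,
400-<800,400,800,4,1,337,,,,1.39,,1.52
"""

def _digest(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


# Frozen digests of the transcriptions above.  Regenerating them requires a
# deliberate edit here, which is the point: silent fixture drift fails loudly.
TABLE1_SHA = "4f52aa208737"
TABLE2_SHA = "507afab9398f"


def load_fixture_tables() -> dict[str, pd.DataFrame]:
    """Return the transcribed summary tables, verifying their checksums."""
    if _digest(TABLE1_CSV) != TABLE1_SHA:
        raise RuntimeError("table1 fixture checksum mismatch: transcription was altered")
    if _digest(TABLE2_CSV) != TABLE2_SHA:
        raise RuntimeError("table2 fixture checksum mismatch: transcription was altered")
    t1 = pd.read_csv(io.StringIO(TABLE1_CSV))
    t2 = pd.read_csv(io.StringIO(TABLE2_CSV))
    return {"table1": t1, "table2": t2}


def table1_percentages() -> dict[str, float]:
    """Headline shares recomputed from the transcribed counts (percent).

    ``controls_of_total`` -- controls as a share of all subjects;
    ``adeno_of_cases`` -- adenocarcinoma share among cases;
    ``cases_among_never_smokers`` -- case share within never smokers.
    """
    t1 = load_fixture_tables()["table1"]
    total = t1[t1["section"] == "total"].iloc[0]
    n_all = total["n_controls"] + total["n_cases"]
    adeno = t1[(t1["section"] == "histology") & (t1["level"] == "AdenoLC")].iloc[0]
    never = t1[(t1["section"] == "smoking") & (t1["level"] == "never")].iloc[0]
    return {
        "controls_of_total": 100.0 * total["n_controls"] / n_all,
        "adeno_of_cases": 100.0 * adeno["n_cases"] / total["n_cases"],
        "cases_among_never_smokers": 100.0
        * never["n_cases"]
        / (never["n_cases"] + never["n_controls"]),
    }
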