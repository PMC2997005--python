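import numpy as np
import pandas as pd
import pytest

from pancmir import CtMatrix, Period, PeriodScheme


@pytest.fixture
def small_scheme() -> PeriodScheme:
    """Two samples per period, quorum 2/2 everywhere."""
    return PeriodScheme(
        [
            Period("early", ("s1", "s2"), min_detected=2),
            Period("mid", ("s3", "s4"), min_detected=2),
            Period("late", ("s5", "s6"), min_detected=2),
        ]
    )


@pytest.fixture
def study_scheme() -> PeriodScheme:
    """The 3/5/2-sample scheme with the 2/4/2 detection quorum."""
    from pancmir import default_mirna_scheme

    return default_mirna_scheme()


@pytest.fixture
def ct_file(tmp_path):
    """A tiny Ct table file in the canonical orientation (miRNA rows)."""
    text = (
        "miRNA\tS1\tS2\tS3\n"
        "miR-7\t22.4\t21.0\t35\n"
        "miR-375\tUndetermined\t28.5\t30.25\n"
        "RNU48\t20.0\t20.5\t19.75\n"
    )
    path = tmp_path / "ct.tsv"
    path.write_text(text)
    return path


@pytest.fixture
def targetscan_file(tmp_path):
    """Five site rows collapsing to three unique human pairs."""
    header = (
        "Gene ID\tGene Symbol\tTranscript ID\tSpecies ID\tmiRNA\t"
        "Site Type\tUTR start\tUTR end\tcontext score\tcontext percentile\n"
    )
    rows = [
        "G1\tFOXA2\tNM_1\t9606\thsa-miR-342\t2\t100\t107\t-0.31\t90",
        "G1\tFOXA2\tNM_1\t9606\thsa-miR-342\t1\t410\t417\t-0.12\t55",  # 2nd site, same pair
        "G2\tNEUROD1\tNM_2\t9606\thsa-miR-17-5p\t3\t55\t62\t-0.45\t97",
        "G3\tSOX9\tNM_3\t9606\thsa-miR-130b\t1\t20\t27\t-0.21\t70",
        "G9\tFOXA2\tXM_9\t10090\tmmu-miR-342\t1\t12\t19\t-0.50\t99",  # non-human
    ]
    path = tmp_path / "targetscan.txt"
    path.write_text(header + "\n".join(rows) + "\n")
    return path


@pytest.fixture
def mirbase_file(tmp_path):
    """Six transcript rows collapsing to four unique gene-level pairs."""
    header = (
        "GROUP\tSEQ\tMETHOD\tFEATURE\tCHR\tSTART\tEND\tSTRAND\tPHASE\t"
        "SCORE\tPVALUE_OG\tTRANSCRIPT_ID\tEXTERNAL_NAME\n"
    )
    rows = [
        "m\thsa-miR-342\tmiranda\tt\t1\t10\t20\t+\t.\t15.1\t0.01\tENST01\tFOXA2",
        "m\thsa-miR-342\tmiranda\tt\t1\t30\t40\t+\t.\t15.9\t0.02\tENST02\tfoxa2",  # 2nd transcript
        "m\thsa-miR-99b\tmiranda\tt\t2\t10\t20\t-\t.\t16.0\t0.01\tENST03\tINSM1",
        "m\thsa-miR-182\tmiranda\tt\t3\t10\t20\t+\t.\t17.2\t0.02\tENST04\tIsl1",
        "m\thsa-miR-182\tmiranda\tt\t3\t50\t60\t+\t.\t17.0\t0.03\tENST05\tISL1",
        "m\thsa-miR-17-5p\tmiranda\tt\t4\t10\t20\t-\t.\t18.0\t0.01\tENST06\tNEUROD1",
    ]
    path = tmp_path / "mirbase.txt"
    path.write_text(header + "\n".join(rows) + "\n")
    return path


def make_ct(rows: dict[str, list[float]], samples: list[str], control="RNU48") -> CtMatrix:
    """Build a CtMatrix from per-miRNA row values (NaN = undetermined)."""
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=samples)
    return CtMatrix(ct=frame.astype(float), control_id=control)


@pytest.fixture
def make_ct_matrix():
    return make_ct
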