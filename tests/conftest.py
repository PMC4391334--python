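import numpy as np
import pandas as pd
import pytest

from methylaudit.io_methylation import BetaMatrix, GenotypeCallMatrix


@pytest.fixture
def small_beta_matrix() -> BetaMatrix:
    """3 probes x 2 samples with one clean value per bin."""
    frame = pd.DataFrame(
        [[0.9, 0.95], [0.5, 0.48], [0.1, 0.02]],
        index=pd.Index(["cg_a", "cg_b", "cg_c"], name="probe_id"),
        columns=["s1", "s2"],
    )
    return BetaMatrix(frame)


@pytest.fixture
def tsv_beta_file(tmp_path):
    path = tmp_path / "beta.tsv"
    path.write_text(
        "probe_id\ts1\ts2\n"
        "cg_a\t0.9\t0.95\n"
        "cg_b\t0.5\t0.48\n"
        "cg_c\t0.1\t0.02\n"
    )
    return path


@pytest.fixture
def geo_beta_file(tmp_path):
    path = tmp_path / "series.txt"
    path.write_text(
        "!Series_title\t\"demo\"\n"
        "!Sample_geo_accession\t\"GSM1\"\t\"GSM2\"\n"
        "!series_matrix_table_begin\n"
        '"ID_REF"\t"GSM1"\t"GSM2"\n'
        '"cg_a"\t0.9\t0.95\n'
        '"cg_b"\t0.5\tNA\n'
        "!series_matrix_table_end\n"
    )
    return path


@pytest.fixture
def annotation_file(tmp_path):
    path = tmp_path / "annotation.csv"
    path.write_text(
        "probe_id,chromosome,position,sequence,cpg_offset\n"
        "cg00000001,16,12345,ATACGTT,3\n"
        "cg11036359,6,29759078,ACCGGT,2\n"
    )
    return path


@pytest.fixture
def call_matrix() -> GenotypeCallMatrix:
    frame = pd.DataFrame(
        [["CC", "CD"], ["DD", np.nan], ["CD", "CC"]],
        index=pd.Index(["cg_a", "cg_b", "cg_c"], name="probe_id"),
        columns=["s1", "s2"],
    )
    return GenotypeCallMatrix(frame)
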