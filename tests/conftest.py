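import io
import textwrap

import pytest

from evlongread.synthetic_data import SimConfig, make_study_fixture
from evlongread.transcript_model import load_annotation

TOY_GTF = textwrap.dedent(
    """\
    chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "GPLUS"; transcript_id "TPLUS"; transcript_biotype "protein_coding";
    chr1\ttest\texon\t301\t450\t.\t+\t.\tgene_id "GPLUS"; transcript_id "TPLUS"; transcript_biotype "protein_coding";
    chr1\ttest\texon\t101\t200\t.\t-\t.\tgene_id "GMINUS"; transcript_id "TMINUS"; transcript_biotype "lncRNA";
    chr1\ttest\texon\t301\t450\t.\t-\t.\tgene_id "GMINUS"; transcript_id "TMINUS"; transcript_biotype "lncRNA";
    """
)


@pytest.fixture
def toy_catalog():
    """Two 2-exon transcripts (exons [100,200)+[300,450)), one per strand."""
    return load_annotation(io.StringIO(TOY_GTF))


@pytest.fixture(scope="session")
def study_fixture(tmp_path_factory):
    """Default 3 Exo + 3 MV study bundle at seed 7 (shared across tests)."""
    out_dir = tmp_path_factory.mktemp("fixture")
    return make_study_fixture(out_dir, seed=7, cfg=SimConfig())
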