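import numpy as np
import pandas as pd
import pytest

from tecsplice.config import AnalysisConfig, SimulationConfig
from tecsplice.models import Annotation, ExpressionMatrix, SampleMeta, TranscriptModel


def make_tx(tid, exons, gene="G1", chrom="chr1", strand="+", cds=None, **kw):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=exons, cds=cds, **kw,
    )


def annotation_of(*transcripts) -> Annotation:
    ann = Annotation()
    for t in transcripts:
        ann.add(t)
    ann.validate()
    return ann


@pytest.fixture
def toy_se_annotation():
    """Three-exon gene with one cleanly skipped cassette exon."""
    t1 = make_tx("t1", [(0, 100), (200, 300), (400, 500)])
    t2 = make_tx("t2", [(0, 100), (400, 500)])
    return annotation_of(t1, t2)


@pytest.fixture
def small_sim_cfg():
    return SimulationConfig(n_genes=60, n_tissues=6, seed=9)


@pytest.fixture
def default_ana_cfg():
    return AnalysisConfig()


def expr_matrix(values: dict, tissues: dict | None = None, level="transcript"):
    df = pd.DataFrame(values)
    metas = [
        SampleMeta(s, (tissues or {}).get(s, s), "peripheral", 1) for s in df.columns
    ]
    return ExpressionMatrix(df, level, metas, "TPM")
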