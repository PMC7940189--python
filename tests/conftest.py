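import numpy as np
import pytest

import motifcircuit as mc
from motifcircuit.forest import ForestConfig


@pytest.fixture(scope="session")
def motif_db():
    """30-motif database, 3 strong plantable motifs + 27 decoys."""
    return mc.make_motif_database(n_motifs=30, n_strong=3, seed=1)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, motif_db):
    """Small fixture bundle shared by file-based tests (40/40/40 genes)."""
    d = tmp_path_factory.mktemp("bundle")
    cfg = mc.SyntheticConfig(
        n_positive=40,
        n_negative1=40,
        n_negative2=40,
        planted_motif_ids=[m.motif_id for m in motif_db[:3]],
        plant_rate_positive=1.0,
        seed=7,
    )
    manifest = mc.write_fixture_bundle(cfg, motif_db, d)
    return {"dir": d, "config": cfg, "manifest": manifest}


def pipeline_config(bundle_dir, out_dir, **overrides):
    defaults = dict(
        de_table=str(bundle_dir / "de.tsv"),
        peaks_bed=str(bundle_dir / "peaks.bed"),
        tss_table=str(bundle_dir / "tss.tsv"),
        genome_fasta=str(bundle_dir / "genome.fa"),
        motif_db=str(bundle_dir / "motifs.meme"),
        out_dir=str(out_dir),
        clusters=["C0"],
        forest=ForestConfig(n_trees=50, seed=3),
        gamma_grid=(0.0, 0.5, 1.0),
        seed=11,
    )
    defaults.update(overrides)
    return mc.PipelineConfig(**defaults)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
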