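import logging
import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles helper module

from hydromine.motifs import load_motif_catalog
from hydromine.pipeline import GenomeInputs, RunConfig, run_pipeline
from hydromine.synthetic import default_panel, generate_panel, write_panel

logging.getLogger("gffutils").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def motif_catalog():
    return load_motif_catalog()


@pytest.fixture(scope="session")
def full_panel():
    """The default eight-genome study panel (seed 42)."""
    return generate_panel(default_panel(seed=42, n_genomes=8))


@pytest.fixture(scope="session")
def full_panel_result(full_panel, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("full_panel")
    manifest = write_panel(full_panel, outdir)
    config = RunConfig(
        reference=manifest["reference"],
        maturation_queries=manifest["maturation_queries"],
        outdir=str(outdir / "results"),
        genomes=[
            GenomeInputs(g["genome_id"], g["proteome"], g["gff"], g["annotations"])
            for g in manifest["genomes"]
        ],
    )
    return config, run_pipeline(config)


@pytest.fixture(scope="session")
def small_panel():
    """Two-genome synthetic panel (seed 42), generated once per session."""
    return generate_panel(default_panel(seed=42, n_genomes=2))


@pytest.fixture(scope="session")
def small_panel_dir(small_panel, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("panel")
    manifest = write_panel(small_panel, outdir)
    return outdir, manifest


@pytest.fixture(scope="session")
def small_panel_result(small_panel_dir):
    """Full pipeline run over the two-genome panel."""
    outdir, manifest = small_panel_dir
    config = RunConfig(
        reference=manifest["reference"],
        maturation_queries=manifest["maturation_queries"],
        outdir=str(outdir / "results"),
        genomes=[
            GenomeInputs(g["genome_id"], g["proteome"], g["gff"], g["annotations"])
            for g in manifest["genomes"]
        ],
    )
    return config, run_pipeline(config)
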