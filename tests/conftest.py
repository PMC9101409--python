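import json

import numpy as np
import pytest

from eccatlas import synthetic_cohort as sc
from eccatlas.io_formats import (
    ReferenceSequence,
    read_circles_bed,
    read_fpkm,
    read_genome_layout,
    read_gtf_transcripts,
)


class Scenario:
    """A built synthetic study plus its loaded artifacts."""

    def __init__(self, config: sc.SyntheticConfig, outdir):
        self.config = config
        self.files = sc.build_cohort(config, outdir)
        self.truth = json.loads(self.files.truth_json.read_text())
        self.cohort = read_circles_bed(self.files.circles_bed)
        self.layout = read_genome_layout(self.files.layout_tsv)
        self.reference = ReferenceSequence(self.files.fasta)

    @property
    def transcripts(self):
        return [t for t in read_gtf_transcripts(self.files.gtf) if t.is_functional]

    @property
    def fpkm(self):
        return read_fpkm(self.files.fpkm_tsv)


@pytest.fixture(scope="session")
def planted_scenario(tmp_path_factory):
    """Cohort with homology and microhomology planted on background circles."""
    config = sc.SyntheticConfig(
        seed=3, homology_plant_fraction=0.5, microhomology_plant_fraction=0.3
    )
    return Scenario(config, tmp_path_factory.mktemp("syn_planted"))


@pytest.fixture(scope="session")
def hotspot_scenario(tmp_path_factory):
    """Short-circle cohort: sparse background, five 90%-penetrance hotspots."""
    config = sc.SyntheticConfig(
        seed=6, circle_length_range=(300, 3000), n_hotspots=5,
        hotspot_penetrance=0.9,
    )
    return Scenario(config, tmp_path_factory.mktemp("syn_hotspot"))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_dna(rng, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))
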