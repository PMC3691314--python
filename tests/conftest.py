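"""Shared fixtures: one seeded synthetic study reused across modules."""

from __future__ import annotations

import pytest

from srnakit.annotate import GenomeIndex, annotate_tags
from srnakit.preprocess import clean_reads, collapse_to_tags
from srnakit.synthdata import SynthConfig, generate_references, simulate_library

FIXTURE_SEED = 7
LIBRARY_SEED = 3


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic study: genome, catalogs, maps, truth."""
    return generate_references(FIXTURE_SEED)


@pytest.fixture(scope="session")
def library(bundle):
    """(reads, realized per-entry counts) under the default conditions."""
    return simulate_library(bundle.truth, seed=LIBRARY_SEED)


@pytest.fixture(scope="session")
def tags(library):
    reads, _ = library
    inserts, _ = clean_reads(reads)
    return collapse_to_tags(inserts)


@pytest.fixture(scope="session")
def genome_index(bundle):
    return GenomeIndex.from_genome(bundle.genome)


@pytest.fixture(scope="session")
def records(tags, genome_index, bundle):
    return annotate_tags(tags, genome_index, bundle.references)


@pytest.fixture(scope="session")
def noise_free():
    """A no-contamination, no-heterogeneity run for exact-recovery checks."""
    cfg = SynthConfig(
        contamination_fraction=0.0, low_quality_fraction=0.0,
        het_3p_fraction=0.0, het_5p_fraction=0.0, n_edits=0,
    )
    bun = generate_references(11, cfg)
    reads, realized = simulate_library(bun.truth, seed=5, config=cfg)
    return cfg, bun, reads, realized


def recovery_config() -> SynthConfig:
    """Small fixture for discovery specificity: 4 true hairpins, 4 decoys."""
    return SynthConfig(
        chrom_lengths={"chr1": 9000, "chr2": 9000},
        n_known_mirnas=0,
        n_novel_mirnas=4,
        n_decoy_loci=4,
        novel_mirna_counts=(350, 260, 200, 150),
        n_pirna_loci=0,
        n_pingpong_loci=0,
        other_classes={},
        n_utrs=4,
        n_target_genes=0,
        mrna_reads=0,
        n_edits=0,
    )
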