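"""Shared fixtures: synthetic bundles and the mapping derived from them.

The medium bundle (150 genes) backs most integration tests; the full
default bundle (500 genes) is reserved for the acceptance suite.  Both
are session-scoped so the simulators run once.
"""

from __future__ import annotations

import pytest

from ribarch import SimulationConfig, simulate_bundle
from ribarch.cds_mapper import (
    map_all_starts,
    peptide_start_anchors,
    prune_conflicting_cds,
)


def apply_pruning(bundle):
    """Drop deleted records and fix strands, as the pipeline does."""
    flags = prune_conflicting_cds(bundle.annotation, bundle.ribo)
    kept = []
    for rec in bundle.annotation:
        f = flags.get(rec.locus, set())
        if "deleted" in f:
            continue
        if "strand_corrected" in f:
            rec.strand = "-" if rec.strand == "+" else "+"
        kept.append(rec)
    return kept, flags


@pytest.fixture(scope="session")
def bundle150():
    return simulate_bundle(SimulationConfig(n_genes=150, ncrna_count=12), seed=1)


@pytest.fixture(scope="session")
def called150(bundle150):
    kept, _ = apply_pruning(bundle150)
    return map_all_starts(bundle150.genome, bundle150.ribo, kept,
                          bundle150.peptides, bundle150.tss)


@pytest.fixture(scope="session")
def anchors150(bundle150):
    return peptide_start_anchors(bundle150.peptides)


@pytest.fixture(scope="session")
def bundle500():
    """The default study-scale bundle used by the acceptance checks."""
    return simulate_bundle(SimulationConfig(), seed=1)
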