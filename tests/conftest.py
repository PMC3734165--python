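"""Shared fixtures: a default synthetic data set, its pipeline run, and
small factories for hand-built domain objects."""

from __future__ import annotations

import pytest

from rootnet import pipeline, synthetic
from rootnet.degradome import CleavageEvidence, ValidatedInteraction
from rootnet.target_scan import BindingSite


@pytest.fixture(scope="session")
def default_dataset(tmp_path_factory):
    """Default-parameter synthetic data set (seed 1), written to disk."""
    out = tmp_path_factory.mktemp("synth_default")
    return synthetic.generate(synthetic.GeneratorConfig(seed=1), out)


@pytest.fixture(scope="session")
def default_run(default_dataset, tmp_path_factory):
    """Full pipeline run over the default synthetic data set."""
    out = tmp_path_factory.mktemp("pipeline_default")
    data_dir = default_dataset.files["transcripts"].parent
    cfg = pipeline.config_for_synthetic(data_dir, out)
    summary = pipeline.run_all(cfg)
    return {"summary": summary, "out_dir": out, "dataset": default_dataset}


def make_site(
    srna_id="s1",
    srna_seq="U" * 20,
    transcript_id="t1",
    start=101,
    penalty=0.0,
) -> BindingSite:
    end = start + len(srna_seq) - 1
    return BindingSite(srna_id, srna_seq, transcript_id, start, end, "|" * len(srna_seq), penalty)


def make_interaction(
    srna_id="s1",
    transcript_id="t1",
    start=101,
    srna_seq="U" * 20,
    canonical=True,
    category=0,
    library_id="DEG1",
) -> ValidatedInteraction:
    site = make_site(srna_id, srna_seq, transcript_id, start)
    p = 10 if canonical else 8
    ev = CleavageEvidence(
        site=site,
        library_id=library_id,
        srna_position=p,
        transcript_position=site.end - p + 1,
        signal_rpm=50.0,
        n_distinct_signatures=2,
        canonical=canonical,
        category=category,
    )
    return ValidatedInteraction(srna_id, transcript_id, site, ev, [library_id], [ev])
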