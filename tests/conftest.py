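from __future__ import annotations

import datetime as dt

import pytest

from coocrdf import (
    CooccurrenceStore,
    EntityAnnotations,
    EntityRef,
    ReferenceRecord,
    ScoringParams,
    SyntheticConfig,
    build_bundle,
    build_neighbor_lists,
    generate,
)

#: seeds for the seeded-corpus oracle-equivalence suite
ORACLE_SEEDS = tuple(range(20))


def make_record(ref_id, mentions, date=None, **kwargs):
    """A minimal reference record for hand-constructed corpora."""
    return ReferenceRecord(
        ref_id=ref_id,
        title=kwargs.pop("title", f"Ref {ref_id}"),
        date=date or dt.date(2020, 1, 1) + dt.timedelta(days=ref_id % 3650),
        journal=kwargs.pop("journal", "J. Test"),
        mentions=frozenset(mentions),
        **kwargs,
    )


def build_store(records, annotations=None, params=None):
    annotations = annotations or EntityAnnotations()
    lists = build_neighbor_lists(records, params or ScoringParams())
    bundle = build_bundle(records, annotations, lists)
    return bundle, CooccurrenceStore.from_bundle(bundle)


@pytest.fixture(scope="session")
def seeded_corpora():
    """Twenty seeded synthetic corpora of 150 references, with stores."""
    out = []
    for seed in ORACLE_SEEDS:
        records, annotations = generate(SyntheticConfig(n_refs=150, seed=seed))
        bundle, store = build_store(records, annotations)
        out.append((records, annotations, bundle, store))
    return out


@pytest.fixture(scope="session")
def one_corpus(seeded_corpora):
    """A single synthetic corpus for tests that need just one."""
    return seeded_corpora[0]
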