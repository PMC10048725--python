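import numpy as np
import pytest

from dinucouple.counts import CompositionTable, compose
from dinucouple.null_models import dimer_probs
from dinucouple.sequence_io import ChromosomeRecord


def make_null_compositions(n, seed, kind="binomial", min_len=15_000, max_len=40_000):
    """Composition tables whose dimer counts are drawn from the null itself.

    Mono counts come from a multinomial over a Dirichlet-varied base
    composition; dimer counts are independent Binomial(W, p_XY) draws
    under the given model, mirroring the replicate sampling scheme.
    """
    rng = np.random.default_rng(seed)
    comps = []
    for i in range(n):
        length = int(rng.integers(min_len, max_len))
        p_base = rng.dirichlet(np.array([30.0, 20.0, 20.0, 30.0]))
        mono = rng.multinomial(length, p_base)
        w = length - 1
        p = dimer_probs(mono, kind)
        comps.append(
            CompositionTable(
                id=f"null{i}",
                species="null",
                length_bp=length,
                n_gaps=0,
                mono_counts=mono.astype(np.int64),
                dimer_counts=rng.binomial(w, p).astype(np.int64),
                valid_windows=w,
            )
        )
    return comps


@pytest.fixture
def record_factory():
    def make(sequence, rec_id="chr1", species="test"):
        rec = ChromosomeRecord(id=rec_id, species=species, sequence=sequence.upper())
        from dinucouple.sequence_io import find_gap_spans

        rec.gap_spans = find_gap_spans(rec.sequence)
        return rec

    return make


@pytest.fixture
def acacaca(record_factory):
    return compose(record_factory("ACACACA"))
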