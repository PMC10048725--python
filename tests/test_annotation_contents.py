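"""Gene/CDS/enhancer/length attributes, dimer classification, pair filtering."""

import numpy as np
import pandas as pd
import pytest

from dinucouple.annotation_contents import (
    GENIC_CLASS,
    LENGTH_CLASS,
    UNCLASSIFIED,
    attribute_dimer_correlations,
    attribute_table,
    classify_dimers,
    enhancer_normalize,
    filter_explained_pairs,
    gene_cds_content,
    is_explained,
)
from dinucouple.correlation_stats import CorrelationRecord
from dinucouple.counts import DIMERS, compose
from dinucouple.null_models import NullModelSpec
from dinucouple.sequence_io import AnnotationSet, ChromosomeRecord
from dinucouple.synthetic_data import SyntheticGenomeSpec, generate_genomes

from conftest import make_null_compositions

# published class lists: length-correlated/genic-anticorrelated vs the reverse
REFERENCE_LENGTH_CLASS = ["AG", "CT", "CC", "GG", "CA", "TG"]
REFERENCE_GENIC_CLASS = ["GA", "TC", "AC", "GT", "GC", "CG"]
REFERENCE_UNCLASSIFIED = ["AA", "TT", "AT", "TA"]


def _record(length, genes=(), mrnas=(), cds=(), gaps=0):
    seq = "ACGT" * (length // 4)
    if gaps:
        seq = "N" * gaps + seq[gaps:]
    ann = AnnotationSet(
        gene_spans=list(genes), mrna_spans=list(mrnas), cds_spans=list(cds)
    )
    rec = ChromosomeRecord(id="c", species="s", sequence=seq, annotations=ann)
    from dinucouple.sequence_io import find_gap_spans

    rec.gap_spans = find_gap_spans(rec.sequence)
    return rec


class TestGeneCdsContent:
    def test_whole_chromosome_gene(self):
        rec = _record(1000, genes=[(0, 1000)])
        c_genes, _ = gene_cds_content(rec)
        assert c_genes == 1.0

    def test_gap_corrected_denominator(self):
        # L = 1000, 100 gap bases, 450 coding bases -> c_CDS = 0.5
        rec = _record(1000, cds=[(100, 550)], gaps=100)
        _, c_cds = gene_cds_content(rec)
        assert c_cds == pytest.approx(0.5)

    def test_no_annotations(self):
        assert gene_cds_content(_record(1000)) == (0.0, 0.0)

    def test_mrna_union_flag(self):
        rec = _record(1000, mrnas=[(0, 200)], cds=[(100, 300)])
        _, with_mrna = gene_cds_content(rec, include_mrna=True)
        _, without = gene_cds_content(rec, include_mrna=False)
        assert with_mrna == pytest.approx(0.3)
        assert without == pytest.approx(0.2)

    def test_all_gap_chromosome_rejected(self):
        rec = _record(100, gaps=100)
        with pytest.raises(ValueError):
            gene_cds_content(rec)


class TestEnhancerNormalize:
    def test_z_scores_with_sample_std(self):
        values, defined = enhancer_normalize([2, 4, 6])
        assert defined
        np.testing.assert_allclose(values, [-1, 0, 1])

    def test_zero_spread_flagged(self):
        values, defined = enhancer_normalize([3, 3, 3])
        assert not defined
        assert (values == 0).all()

    def test_single_chromosome_rejected(self):
        with pytest.raises(ValueError):
            enhancer_normalize([5])

    def test_translation_and_scale_invariance(self):
        base, _ = enhancer_normalize([2, 4, 6, 10])
        shifted, _ = enhancer_normalize([7 + 3 * v for v in [2, 4, 6, 10]])
        np.testing.assert_allclose(base, shifted)


class TestAttributeCorrelations:
    def test_null_attribute_mostly_insignificant(self):
        comps = make_null_compositions(40, seed=10)
        rng = np.random.default_rng(11)
        attrs = pd.DataFrame(
            {
                "id": [c.id for c in comps],
                "gene_content": rng.random(40),
                "cds_content": rng.random(40),
                "enhancer_norm": rng.normal(size=40),
                "length_bp": [c.length_bp for c in comps],
            }
        )
        sig = attribute_dimer_correlations(comps, attrs, NullModelSpec(replicates=10, seed=12))
        vals = sig[["gene_content", "cds_content", "enhancer_norm"]].to_numpy().ravel()
        assert np.mean(np.abs(vals) <= 3) >= 0.95

    def test_planted_cds_gc_bias_detected(self):
        # chromosomes with varying gene density, each with GC-dimer-enriched
        # CDS sequence: GC content must track cds_content
        records = []
        for i in range(25):
            spec = SyntheticGenomeSpec(
                chromosomes_per_genome=1,
                length=30_000,
                gene_density=0.1 + 0.6 * i / 24,
                cds_gc_dimer_bias=0.01,
                seed=130 + i,
            )
            (rec,) = generate_genomes(spec)
            rec.id = f"cds_bias_{i}"
            records.append(rec)
        comps = [compose(r) for r in records]
        attrs = attribute_table(records)
        sig = attribute_dimer_correlations(comps, attrs, NullModelSpec(replicates=10, seed=15))
        assert sig.loc["GC", "cds_content"] > 1.0


class TestClassification:
    @pytest.fixture
    def reference_significances(self):
        """Significance pattern matching the published attribute table."""
        sig = pd.DataFrame(0.0, index=list(DIMERS),
                           columns=["gene_content", "cds_content", "enhancer_norm", "length_bp"])
        for d in REFERENCE_LENGTH_CLASS:
            sig.loc[d, "length_bp"] = 2.0
            sig.loc[d, "gene_content"] = -2.0
            sig.loc[d, "cds_content"] = -2.0
        for d in REFERENCE_GENIC_CLASS:
            sig.loc[d, "length_bp"] = -2.0
            sig.loc[d, "gene_content"] = 2.0
            sig.loc[d, "cds_content"] = 2.0
        # AT: correlated with both length and CDS (the published anomaly)
        sig.loc["AT", "length_bp"] = 2.0
        sig.loc["AT", "cds_content"] = 2.0
        return sig

    def test_reference_pattern_reproduces_published_classes(self, reference_significances):
        classification = classify_dimers(reference_significances)
        for d in REFERENCE_LENGTH_CLASS:
            assert classification[d] == LENGTH_CLASS
        for d in REFERENCE_GENIC_CLASS:
            assert classification[d] == GENIC_CLASS
        for d in REFERENCE_UNCLASSIFIED:
            assert classification[d] == UNCLASSIFIED

    def test_all_zero_significances_unclassified(self):
        sig = pd.DataFrame(0.0, index=list(DIMERS),
                           columns=["gene_content", "cds_content", "length_bp"])
        classification = classify_dimers(sig)
        assert all(classification[d] == UNCLASSIFIED for d in DIMERS)


class TestFilterExplainedPairs:
    def _rec(self, a, b, sig):
        return CorrelationRecord(pair=(a, b), r_empirical=0.5, model_mean=0.0,
                                 model_std=0.1, significance=sig)

    @pytest.fixture
    def classification(self):
        sig = pd.DataFrame(0.0, index=list(DIMERS),
                           columns=["gene_content", "cds_content", "length_bp"])
        for d in REFERENCE_LENGTH_CLASS:
            sig.loc[d, "length_bp"] = 2.0
        for d in REFERENCE_GENIC_CLASS:
            sig.loc[d, "gene_content"] = 2.0
        return classify_dimers(sig)

    def test_same_class_correlated_pair_is_explained(self, classification):
        rec = self._rec("GA", "TC", 3.0)  # both genic, correlated
        assert is_explained(rec, classification)
        assert filter_explained_pairs([rec], classification) == []

    def test_cross_class_anticorrelated_pair_is_explained(self, classification):
        rec = self._rec("GA", "AG", -3.0)
        assert is_explained(rec, classification)

    def test_unclassified_pair_retained(self, classification):
        rec = self._rec("TT", "AA", 6.26)
        retained = filter_explained_pairs([rec], classification)
        assert retained == [rec]

    def test_insignificant_pairs_never_retained(self, classification):
        rec = self._rec("TT", "AA", 0.5)
        assert filter_explained_pairs([rec], classification) == []

    def test_filter_is_idempotent_and_subset(self, classification):
        records = [
            self._rec("GA", "TC", 3.0),
            self._rec("TT", "AA", 6.0),
            self._rec("GC", "CA", 1.7),
            self._rec("AG", "GA", -2.0),
            self._rec("CC", "GG", 0.2),
        ]
        retained = filter_explained_pairs(records, classification)
        assert set(r.pair for r in retained) <= {r.pair for r in records}
        assert filter_explained_pairs(retained, classification) == retained

    def test_reference_tables_consistency(self, classification):
        """Every published retained pair has an unclassified dimer or is a
        printed exception (GC/CG pairs crossing the classification)."""
        from dinucouple.coupling_detection import load_reference_pair_table

        exceptions = {("GC", "CA"), ("GC", "TG"), ("GC", "GA"), ("GC", "TC"), ("CG", "GC")}
        unclassified = set(REFERENCE_UNCLASSIFIED)
        for _, row in load_reference_pair_table().iterrows():
            pair = (row["dimer1"], row["dimer2"])
            assert (
                pair[0] in unclassified
                or pair[1] in unclassified
                or pair in exceptions
                or tuple(reversed(pair)) in exceptions
            )


def test_attribute_table_groups_enhancer_norm_by_genome(record_factory):
    records = []
    for i, species in enumerate(["s1", "s1", "s1", "s2"]):
        rec = record_factory("ACGT" * 250, rec_id=f"c{i}", species=species)
        rec.annotations.enhancer_spans = [(j, j + 10) for j in range(0, (i + 1) * 20, 20)]
        records.append(rec)
    frame = attribute_table(records)
    s1 = frame[frame["species"] == "s1"]["enhancer_norm"]
    assert s1.mean() == pytest.approx(0.0)
    assert s1.std(ddof=1) == pytest.approx(1.0)
    # single-chromosome genome gets no normalized value
    assert frame[frame["species"] == "s2"]["enhancer_norm"].isna().all()
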