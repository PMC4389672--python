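"""E/OP/IA/IM classification, decomposition metrics, accuracy, CV harness."""

import itertools
import random
from fractions import Fraction

import pytest

from domsign import evaluate as ev
from domsign import synthetic as syn
from domsign.core import ECNumber, ProteinRecord, make_signature, parse_ec


def ec(s):
    return parse_ec(s)


class TestClassify:
    @pytest.mark.parametrize(
        "pe, te, expected",
        [
            ("1.2.3.4", "1.2.3.4", ev.Category.E),
            ("1.2.1.1", "1.2.3.4", ev.Category.OP),
            ("1.2.-.-", "1.2.3.4", ev.Category.IA),
            ("1.2.3.4", "1.2.3.-", ev.Category.IM),
            (None, None, ev.Category.E),
            ("1.1.1.1", None, ev.Category.OP),
            (None, "1.2.3.4", ev.Category.IA),
        ],
    )
    def test_printed_cases(self, pe, te, expected):
        pe_label = ec(pe) if pe else None
        te_label = ec(te) if te else None
        assert ev.classify(pe_label, te_label).category is expected

    def test_totality_exhaustive(self):
        """Every (depth, depth, first-mismatch-position) combination plus the
        Non-enzyme cases lands in exactly one category."""
        labels = [None]
        base = ["1", "2", "3", "4"]
        for depth in range(1, 5):
            # correct prefix of 1.2.3.4, plus variants mismatching at each position
            labels.append(ECNumber(tuple(base[:depth])))
            for mism in range(depth):
                toks = list(base[:depth])
                toks[mism] = "9"
                labels.append(ECNumber(tuple(toks)))
        seen = set()
        for pe, te in itertools.product(labels, repeat=2):
            outcome = ev.classify(pe, te)
            assert outcome.category in ev.Category
            seen.add(outcome.category)
        assert seen == set(ev.Category)

    def test_ia_pairs_have_no_mismatched_digits(self):
        labels = [None, ec("1.1"), ec("1.1.1.1"), ec("1.2.3.4"), ec("2.7.-.-")]
        for pe, te in itertools.product(labels, repeat=2):
            outcome = ev.classify(pe, te)
            if outcome.category is ev.Category.IA and outcome.pe is not None:
                common = min(outcome.pe.depth, outcome.te.depth)
                assert outcome.pe.tokens[:common] == outcome.te.tokens[:common]

    def test_prediction_result_statuses_count_as_non_enzyme(self, worked_model):
        from domsign.core import PredictionResult, Status

        for status in (Status.NO_DOMAIN, Status.NON_ENZYME, Status.UNRESOLVED_ENZYME):
            res = PredictionResult(id="q", status=status)
            assert ev.classify(res, None).category is ev.Category.E
            assert ev.classify(res, ec("1.1.1.1")).category is ev.Category.IA


class TestDecompose:
    def test_partial_label(self):
        assert ev.decompose(ec("1.1.-.-")) == {"1", "1.1", "1.1.-", "1.1.-.-"}

    def test_full_depth_label(self):
        assert ev.decompose(ec("1.1.2.3")) == {"1", "1.1", "1.1.2", "1.1.2.3"}

    def test_non_enzyme_singleton(self):
        assert ev.decompose(None) == {ev.NON_ENZYME_LABEL}


class TestExampleMetrics:
    def test_identical_full_depth(self):
        pairs = [(ec("1.1.2.3"), ec("1.1.2.3"))] * 5
        assert ev.example_metrics(pairs) == (1.0, 1.0)

    def test_half_overlap(self):
        precision, recall = ev.example_metrics([(ec("1.1.-.-"), ec("1.1.2.3"))])
        assert precision == 0.5 and recall == 0.5

    def test_non_enzyme_vs_enzyme_disjoint(self):
        assert ev.example_metrics([(None, ec("1.1.2.3"))]) == (0.0, 0.0)

    def test_empty_is_error(self):
        with pytest.raises(Exception):
            ev.example_metrics([])

    def test_precision_equals_recall_at_full_depth(self):
        rng = random.Random(5)
        pairs = []
        for _ in range(30):
            a = ECNumber(tuple(str(rng.randint(1, 3)) for _ in range(4)))
            b = ECNumber(tuple(str(rng.randint(1, 3)) for _ in range(4)))
            pairs.append((a, b))
        precision, recall = ev.example_metrics(pairs)
        assert precision == recall


class TestAccuracy:
    def test_exact_predictions_are_perfect(self):
        pairs = [(ec("1.2.3.4"), ec("1.2.3.4"))] * 4
        for level in (1, 2, 3, 4):
            assert ev.accuracy_at_level(pairs, level) == 1.0

    def test_insufficient_depth_counts_incorrect(self):
        pairs = [(ec("1.2.-.-"), ec("1.2.3.4"))]
        assert ev.accuracy_at_level(pairs, 2) == 1.0
        assert ev.accuracy_at_level(pairs, 3) == 0.0

    def test_mixed_fraction(self):
        pairs = [
            (ec("1.2.3.4"), ec("1.2.3.4")),
            (ec("1.2.3.4"), ec("1.2.9.9")),
            (ec("1.2.-.-"), ec("1.2.3.4")),
            (ec("1.9.1.1"), ec("1.2.3.4")),
        ]
        assert ev.accuracy_at_level(pairs, 2) == 0.75

    def test_no_eligible_truths_is_error(self):
        with pytest.raises(Exception):
            ev.accuracy_at_level([(ec("1.1.1.1"), ec("1.1"))], 3)


class TestSubsubfamilyFilter:
    def _family(self, prefix, n):
        return [
            ProteinRecord(id=f"{prefix}-{i}", ec=parse_ec(f"{prefix}.{i % 3 + 1}"))
            for i in range(n)
        ]

    def test_small_families_dropped(self):
        records = self._family("1.1.1", 49) + self._family("2.7.11", 60)
        kept = ev.filter_min_subsubfamily(records)
        assert len(kept) == 60
        assert all(r.ec.tokens[:3] == ("2", "7", "11") for r in kept)

    def test_boundary_family_of_exactly_min_retained(self):
        records = self._family("1.1.1", 50)
        assert len(ev.filter_min_subsubfamily(records)) == 50

    def test_min_one_is_identity(self):
        records = self._family("1.1.1", 3)
        assert ev.filter_min_subsubfamily(records, min_members=1) == records


def pure_group_corpus():
    """Ten pure DS groups of 20 members each, plus non-colliding non-enzymes."""
    groups = tuple(
        syn.GroupSpec(ec_counts=((f"{c}.{s}.1.1", 20),))
        for c, s in [(1, 1), (1, 2), (2, 1), (2, 3), (3, 1), (3, 2), (4, 1), (4, 2), (5, 1), (6, 1)]
    )
    nonenzyme = tuple(syn.NonEnzymeGroupSpec(member_count=5) for _ in range(4))
    return syn.CorpusSpec(groups=groups, nonenzyme_groups=nonenzyme, seed=3)


class TestCrossValidate:
    def test_pure_groups_give_equality_for_enzymes(self):
        enzymes, nonenzymes = syn.generate(pure_group_corpus())
        report = ev.cross_validate(
            enzymes + nonenzymes, nonenzymes, k=10, threshold=Fraction(4, 5), seed=17
        )
        # every enzyme query shares its DS with many training copies of one EC;
        # non-enzyme DSs are removed by the specific-DS subtraction, so all
        # classified pairs are Equality
        assert report.categories[ev.Category.E] == report.n_classified
        assert report.fractions["E"] == 1.0
        assert abs(sum(report.fractions.values()) - 1.0) < 1e-12

    def test_leave_one_out_on_singletons_is_ia_dominated(self):
        groups = tuple(
            syn.GroupSpec(ec_counts=((f"{i + 1}.1.1.1", 1),)) for i in range(6)
        )
        enzymes, _ = syn.generate(syn.CorpusSpec(groups=groups))
        report = ev.cross_validate(enzymes, [], k=len(enzymes), seed=1)
        # each held-out DS is unseen in training: never annotated, always IA
        assert report.categories[ev.Category.IA] == report.n_classified

    def test_same_seed_reproduces_report(self):
        enzymes, nonenzymes = syn.generate(pure_group_corpus())
        r1 = ev.cross_validate(enzymes + nonenzymes, nonenzymes, k=5, seed=7)
        r2 = ev.cross_validate(enzymes + nonenzymes, nonenzymes, k=5, seed=7)
        assert r1.categories == r2.categories
        assert r1.precision == r2.precision
        assert [f.categories for f in r1.folds] == [f.categories for f in r2.folds]

    def test_multi_ec_truth_rejected(self):
        enzymes, _ = syn.generate(pure_group_corpus())
        bad = ProteinRecord(
            id="M", signature=make_signature(["PFTEST77777"]), multi_ec=True
        )
        with pytest.raises(Exception, match="multiple EC"):
            ev.cross_validate(enzymes + [bad], [], k=5, seed=0)

    def test_raising_threshold_never_raises_op(self):
        """Directional sweep: stricter thresholds trade coverage for precision."""
        rng = random.Random(42)
        enzymes = []
        while len(enzymes) < 60:
            enzymes, nonenzymes = syn.generate(syn.random_corpus_spec(rng, max_groups=6))
        noisy = syn.perturb_labels(enzymes, 0.3, seed=8)
        previous_op = None
        previous_shallow = None
        for t in [Fraction(7, 10), Fraction(4, 5), Fraction(9, 10), Fraction(99, 100)]:
            report = ev.cross_validate(noisy + nonenzymes, nonenzymes, k=4, threshold=t, seed=2)
            op = report.categories[ev.Category.OP]
            shallow = report.n_classified - sum(
                report.depth_distribution.get(d, 0) for d in (1, 2, 3, 4)
            )
            if previous_op is not None:
                assert op <= previous_op
                assert shallow >= previous_shallow
            previous_op, previous_shallow = op, shallow


class TestEvaluatePredictions:
    def test_report_fields(self, worked_model, worked_corpus):
        from domsign import predict as pr

        enzymes, nonenzymes = worked_corpus
        records = enzymes + nonenzymes
        results = pr.predict_batch(
            records, worked_model.models, worked_model.specific_ds,
            pr.EngineConfig(threshold=Fraction(4, 5)),
        )
        report = ev.evaluate_predictions(results, records)
        assert report["n"] == len(records)
        total = sum(report[f"count_{c.value}"] for c in ev.Category)
        assert total == len(records)
        # worked group: depth-3 prediction vs depth-4 truths -> IA for correct
        # prefixes, OP for members of the other subgroups
        assert report["count_IA"] > 0
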