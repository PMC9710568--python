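import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ablm.model import likelihoods
from ablm.restoration import (
    GermlineDB,
    RestorationResult,
    assign_germline,
    benchmark_nterm,
    benchmark_random_sites,
    germline_restorer,
    restore_germline,
    restore_masked,
    restore_nterm,
)
from ablm.sequences import AMINO_ACIDS, WILDCARD, AntibodySequence, SequenceError
from ablm.synthetic_data import (
    GeneratorConfig,
    complete_truncation_distribution,
    generate,
    truth_numberer,
)


class TestRestoreMasked:
    def test_fills_every_wildcard_from_argmax(self, untrained_tiny, seq):
        s = seq("E*QLV")
        res = restore_masked(untrained_tiny, s)
        assert WILDCARD not in res.restored.residues
        p = likelihoods(untrained_tiny, s)
        assert res.restored.residues[1] == AMINO_ACIDS[int(p[1].argmax())]
        assert res.per_position.keys() == {1}
        aa, prob = res.per_position[1]
        assert prob == pytest.approx(p[1].max())

    def test_all_wildcards_single_pass(self, untrained_tiny, seq):
        res = restore_masked(untrained_tiny, seq("*****"))
        assert len(res.restored.residues) == 5
        assert set(res.per_position) == set(range(5))

    def test_no_wildcard_is_warned_noop(self, untrained_tiny, seq):
        res = restore_masked(untrained_tiny, seq("EVQLV"))
        assert res.restored.residues == "EVQLV"
        assert res.warning is not None
        assert res.per_position == {}

    def test_substituted_probability_is_row_maximum(self, untrained_tiny, seq):
        s = seq("EV*LVES*G")
        res = restore_masked(untrained_tiny, s)
        p = likelihoods(untrained_tiny, s)
        for i, (aa, prob) in res.per_position.items():
            best = max(p[i, j] for j in range(20))
            assert prob == pytest.approx(best)


@settings(derandomize=True, max_examples=30)
@given(
    residues=st.text(alphabet=AMINO_ACIDS + "*", min_size=2, max_size=40).filter(
        lambda t: "*" in t
    )
)
def test_known_residues_never_change(untrained_tiny, residues):
    s = AntibodySequence("h", "heavy", residues)
    res = restore_masked(untrained_tiny, s)
    for a, b in zip(residues, res.restored.residues):
        if a != WILDCARD:
            assert a == b


class TestNtermSearch:
    def test_candidate_window_size(self, untrained_tiny, heavy5):
        cfg = GeneratorConfig(
            n_sequences=30, germlines=heavy5, ambiguous_rate=0.0, seed=5
        )
        seqs, gt = generate(cfg)
        nb = truth_numberer(gt)
        s = next(x for x in seqs if gt[x.id].truncation >= 8)
        m = nb.standard_missing(s)
        res = restore_nterm(untrained_tiny, s, nb, rounds=1)
        # 11 candidates m-8 .. m+2; winner within that window
        assert m - 8 <= res.n_prepended <= m + 2

    def test_selected_candidate_maximizes_first_residue_likelihood(
        self, untrained_tiny, heavy5
    ):
        cfg = GeneratorConfig(
            n_sequences=10, germlines=heavy5, ambiguous_rate=0.0, seed=6
        )
        seqs, gt = generate(cfg)
        nb = truth_numberer(gt)
        s = seqs[0]
        m = nb.standard_missing(s)
        res = restore_nterm(untrained_tiny, s, nb, rounds=1)
        # replay every candidate and verify none scores higher
        for k in range(max(0, m - 8), m + 3):
            cand = s.with_residues(WILDCARD * k + s.residues)
            replay = restore_masked(untrained_tiny, cand)
            assert replay.first_residue_likelihood <= res.first_residue_likelihood + 1e-12

    def test_internal_wildcard_rejected(self, untrained_tiny, seq, repertoire):
        _, gt = repertoire
        nb = truth_numberer(gt)
        with pytest.raises(SequenceError):
            restore_nterm(untrained_tiny, seq("EV*LV"), nb)

    def test_invalid_rounds_rejected(self, untrained_tiny, seq, repertoire):
        _, gt = repertoire
        nb = truth_numberer(gt)
        with pytest.raises(ValueError):
            restore_nterm(untrained_tiny, seq("EVQLV"), nb, rounds=3)


@pytest.fixture(scope="module")
def unmutated(heavy5):
    cfg = GeneratorConfig(
        n_sequences=40,
        germlines=heavy5,
        mutation_rate=0.0,
        ambiguous_rate=0.0,
        seed=8,
    )
    return generate(cfg)


class TestGermlineRestorer:
    def test_unmutated_truncations_restored_exactly(self, unmutated, heavy5):
        seqs, gt = unmutated
        nb = truth_numberer(gt)
        for s in seqs:
            rec = gt[s.id]
            if rec.truncation == 0:
                continue
            res = restore_germline(s, heavy5, nb)
            assert res.restored.residues == rec.full_residues
            assert res.n_prepended == rec.truncation
            assert res.allele == rec.allele
            assert res.identity == pytest.approx(1.0)

    def test_mutated_position_predicts_germline_not_truth(self, heavy5):
        """The baseline predicts the unmutated residue: masking a mutated
        site recovers the germline amino acid, not the somatic one."""
        cfg = GeneratorConfig(
            n_sequences=60,
            germlines=heavy5,
            mutation_rate=0.04,
            truncation_distribution=complete_truncation_distribution(),
            ambiguous_rate=0.0,
            seed=9,
        )
        seqs, gt = generate(cfg)
        nb = truth_numberer(gt)
        checked = 0
        for s in seqs:
            rec = gt[s.id]
            if len(rec.mutated_positions) < 1:
                continue
            i = rec.mutated_positions[0]
            body = list(s.residues)
            true_residue = body[i]
            body[i] = WILDCARD
            from dataclasses import replace

            masked = replace(s, residues="".join(body))
            res = restore_germline(masked, heavy5, nb)
            germ = heavy5[rec.allele].residues[i]
            assert res.per_position[i][0] == germ
            assert germ != true_residue
            checked += 1
            if checked >= 10:
                break
        assert checked >= 5

    def test_identity_matches_brute_force(self, unmutated, heavy5):
        seqs, gt = unmutated
        nb = truth_numberer(gt)
        s = seqs[0]
        rec = gt[s.id]
        name, ident = assign_germline(s, heavy5, nb)
        germ = heavy5[name]
        gmap = germ.position_map
        numbering = nb.number(s)
        matches = aligned = 0
        for pos, i in numbering:
            if pos in gmap:
                aligned += 1
                matches += gmap[pos] == s.residues[i]
        assert ident == pytest.approx(matches / aligned)

    def test_tie_breaks_lexicographically(self, seq):
        db = GermlineDB.from_fasta_records = None  # guard against misuse
        from ablm.restoration import GermlineRecord

        recs = {
            "B*01": GermlineRecord("B*01", "heavy", "EVQ", ("1", "2", "3")),
            "A*01": GermlineRecord("A*01", "heavy", "EVQ", ("1", "2", "3")),
        }
        db = GermlineDB(recs)
        s = seq("EVQ", numbering=(("1", 0), ("2", 1), ("3", 2)))
        name, ident = assign_germline(s, db)
        assert name == "A*01" and ident == pytest.approx(1.0)

    def test_uncovered_position_left_as_wildcard(self, seq):
        from ablm.restoration import GermlineRecord

        db = GermlineDB({"A*01": GermlineRecord("A*01", "heavy", "EV", ("1", "2"))})
        s = seq("E*Q", numbering=(("1", 0), ("5", 1), ("6", 2)))
        res = restore_germline(s, db, complete_nterm=False)
        assert res.restored.residues == "E*Q"
        assert res.failed_positions == (1,)


class _OracleRestorer:
    """Perfect restorer: looks the truth up from the ground-truth table."""

    def __init__(self, truth):
        self.truth = truth

    def __call__(self, seq):
        rec = self.truth[seq.id]
        full = rec.full_residues
        offset = len(full) - len(seq.residues)
        body = [
            full[offset + i] if c == WILDCARD else c for i, c in enumerate(seq.residues)
        ]
        from dataclasses import replace

        return RestorationResult(
            restored=replace(seq, residues="".join(body)),
            n_prepended=0,
            first_residue_likelihood=1.0,
            per_position={},
        )


class _UniformRandomRestorer:
    def __init__(self, seed=0):
        self.rng = np.random.default_rng(seed)

    def __call__(self, seq):
        body = [
            AMINO_ACIDS[self.rng.integers(20)] if c == WILDCARD else c
            for c in seq.residues
        ]
        from dataclasses import replace

        return RestorationResult(
            restored=replace(seq, residues="".join(body)),
            n_prepended=0,
            first_residue_likelihood=0.05,
            per_position={},
        )


@pytest.fixture(scope="module")
def complete_set(heavy5):
    cfg = GeneratorConfig(
        n_sequences=30,
        germlines=heavy5,
        mutation_rate=0.03,
        truncation_distribution=complete_truncation_distribution(),
        ambiguous_rate=0.0,
        seed=10,
    )
    return generate(cfg)


class TestBenchmarks:
    def test_oracle_restorer_perfect_at_every_length(self, complete_set):
        seqs, gt = complete_set
        table = benchmark_nterm(_OracleRestorer(gt), seqs[:10], max_missing=10)
        assert (table["accuracy"] == 1.0).all()
        assert list(table["missing_length"]) == list(range(1, 11))

    def test_uniform_restorer_near_chance(self, complete_set):
        seqs, _ = complete_set
        table = benchmark_nterm(_UniformRandomRestorer(0), seqs, max_missing=20)
        overall = table["accuracy"].mean()
        assert abs(overall - 0.05) < 0.03

    def test_germline_restorer_perfect_on_unmutated_data(self, heavy5):
        cfg = GeneratorConfig(
            n_sequences=15,
            germlines=heavy5,
            mutation_rate=0.0,
            truncation_distribution=complete_truncation_distribution(),
            ambiguous_rate=0.0,
            seed=11,
        )
        seqs, gt = generate(cfg)
        nb = truth_numberer(gt)
        table = benchmark_nterm(germline_restorer(heavy5, nb), seqs, max_missing=15)
        assert (table["accuracy"] == 1.0).all()

    def test_random_sites_deterministic_under_seed(self, complete_set):
        seqs, gt = complete_set
        r = _OracleRestorer(gt)
        a = benchmark_random_sites(r, seqs, n_masked=5, seed=3)
        b = benchmark_random_sites(r, seqs, n_masked=5, seed=3)
        assert a == b == 1.0

    def test_random_sites_uniform_near_chance(self, complete_set):
        seqs, _ = complete_set
        acc = benchmark_random_sites(_UniformRandomRestorer(1), seqs, n_masked=10, seed=0)
        assert abs(acc - 0.05) < 0.04

    def test_short_sequences_skipped(self, complete_set, seq):
        seqs, gt = complete_set
        acc = benchmark_random_sites(_OracleRestorer(gt), seqs, n_masked=200, seed=0)
        assert np.isnan(acc)
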