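import numpy as np
import pytest

from _oracles import oracle_best, oracle_mfe_alignment
from saltnet.duplex import (
    STACK_TABLE,
    DuplexAlignment,
    State,
    align_duplex,
    allen_score,
    duplex_mfe,
    predict_targets,
    scan_best_sites,
)
from saltnet.models import InputError, revcomp_rna

RNG = np.random.default_rng(20240101)
NTS = np.array(list("ACGU"))


def rand_rna(n, rng=RNG):
    return "".join(rng.choice(NTS, size=n))


def make_aln(states, mirna):
    mfe, perfect, ratio = duplex_mfe(states, mirna)
    return DuplexAlignment(
        mirna_id="m", target_id="t", site_start=0, site_end=0,
        mirna_seq=mirna, site_seq="", states=tuple(states),
        allen_score=allen_score(states), mfe=mfe, mfe_perfect=perfect,
        mfe_ratio=ratio,
    )


class TestAllenScore:
    def test_all_paired_is_zero(self):
        assert allen_score([State.WC_pair] * 21) == 0.0

    def test_core_doubling(self):
        # mismatch at position 1 (outside core) costs 1
        states = [State.mismatch] + [State.WC_pair] * 20
        assert allen_score(states) == 1.0
        # mismatch at position 2 (core) costs 2
        states = [State.WC_pair, State.mismatch] + [State.WC_pair] * 19
        assert allen_score(states) == 2.0
        # mismatch at position 14 (past core) costs 1 again
        states = [State.WC_pair] * 13 + [State.mismatch] + [State.WC_pair] * 7
        assert allen_score(states) == 1.0

    def test_wobble_costs_half(self):
        states = [State.GU_wobble] + [State.WC_pair] * 20
        assert allen_score(states) == 0.5
        states = [State.WC_pair] * 5 + [State.GU_wobble] + [State.WC_pair] * 15
        assert allen_score(states) == 1.0  # inside core

    def test_target_bulge_doubled_when_flanking_core(self):
        # bulge after position 1: flanked by 1 and 2 -> core-adjacent, cost 2
        states = [State.WC_pair, State.bulge_target] + [State.WC_pair] * 20
        assert allen_score(states) == 2.0
        # bulge after position 13: flanked by 13 and 14 -> 13 in core, cost 2
        states = [State.WC_pair] * 13 + [State.bulge_target] + [State.WC_pair] * 8
        assert allen_score(states) == 2.0
        # bulge after position 14: cost 1
        states = [State.WC_pair] * 14 + [State.bulge_target] + [State.WC_pair] * 7
        assert allen_score(states) == 1.0


class TestAlignDuplex:
    def test_perfect_complement_all_lengths(self):
        rng = np.random.default_rng(1)
        for L in range(18, 26):
            m = rand_rna(L, rng)
            aln = align_duplex(m, revcomp_rna(m))
            assert aln.allen_score == 0.0
            assert aln.mfe_ratio == 1.0
            assert all(s is State.WC_pair for s in aln.states)

    def test_length_validation(self):
        with pytest.raises(InputError):
            align_duplex(rand_rna(17), rand_rna(20))
        with pytest.raises(InputError):
            align_duplex(rand_rna(26), rand_rna(26))

    def test_short_site_refused(self):
        m = rand_rna(21)
        with pytest.raises(InputError):
            align_duplex(m, rand_rna(17))  # < 21 - 3
        align_duplex(m, rand_rna(18))  # boundary accepted

    def test_single_mismatch_detected(self):
        rng = np.random.default_rng(2)
        m = rand_rna(21, rng)
        site = list(revcomp_rna(m))
        # corrupt the site base pairing miRNA position 5 into a hard mismatch
        idx = 21 - 5
        bad = {"A": "C", "C": "A", "G": "G", "U": "U"}[m[4]]
        site[idx] = bad
        aln = align_duplex(m, "".join(site))
        assert aln.allen_score == 2.0  # mismatch in core
        assert aln.states[4] is State.mismatch

    def test_matches_independent_oracle_on_valid_lengths(self):
        rng = np.random.default_rng(3)
        for _ in range(150):
            L = int(rng.integers(18, 26))
            m = rand_rna(L, rng)
            site = rand_rna(int(rng.integers(L - 3, L + 6)), rng)
            aln = align_duplex(m, site)
            half, _ = oracle_best(m, site)
            assert aln.allen_score == half / 2.0

    def test_state_count_invariant(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            m = rand_rna(20, rng)
            site = rand_rna(22, rng)
            aln = align_duplex(m, site)
            consumed = sum(1 for s in aln.states if s is not State.bulge_target)
            assert consumed == len(m)
            site_consumed = sum(
                1 for s in aln.states if s is not State.bulge_mirna
            )
            assert site_consumed == len(site)


class TestDuplexMfe:
    def test_stack_table_is_rc_symmetric(self):
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for ab, e in STACK_TABLE.items():
            rc = comp[ab[1]] + comp[ab[0]]
            assert STACK_TABLE[rc] == e

    def test_matches_stack_walk_oracle(self):
        rng = np.random.default_rng(5)
        kinds = [
            State.WC_pair, State.GU_wobble, State.mismatch,
            State.bulge_mirna, State.bulge_target,
        ]
        checked = 0
        while checked < 60:
            m = rand_rna(int(rng.integers(18, 26)), rng)
            states = []
            consumed = 0
            while consumed < len(m):
                s = kinds[int(rng.integers(len(kinds)))]
                states.append(s)
                if s is not State.bulge_target:
                    consumed += 1
            aln = make_aln(states, m)
            assert aln.mfe == pytest.approx(oracle_mfe_alignment(aln))
            checked += 1

    def test_no_pairs_degenerate(self):
        m = rand_rna(20)
        mfe, perfect, ratio = duplex_mfe([State.mismatch] * 20, m)
        assert mfe == 0.0 and ratio == 0.0 and perfect < 0

    def test_ratio_clamped_to_unit_interval(self):
        rng = np.random.default_rng(6)
        for _ in range(50):
            m = rand_rna(20, rng)
            site = rand_rna(21, rng)
            aln = align_duplex(m, site)
            assert 0.0 <= aln.mfe_ratio <= 1.0

    def test_reverse_complement_energy_invariance(self):
        """Reversing an all-column-paired duplex and complementing the miRNA
        leaves the energy unchanged (the stack table is rc-symmetric)."""
        rng = np.random.default_rng(7)
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(40):
            m = rand_rna(20, rng)
            states = [
                State.WC_pair if rng.random() < 0.7 else State.mismatch
                for _ in range(20)
            ]
            mfe_fwd, _, _ = duplex_mfe(states, m)
            m_rc = "".join(comp[c] for c in reversed(m))
            mfe_rev, _, _ = duplex_mfe(states[::-1], m_rc)
            assert mfe_fwd == pytest.approx(mfe_rev)

    def test_breaking_a_pair_never_improves_ratio(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            m = rand_rna(21, rng)
            states = [State.WC_pair] * 21
            _, _, base = duplex_mfe(states, m)
            k = int(rng.integers(0, 21))
            states[k] = State.mismatch
            _, _, worse = duplex_mfe(states, m)
            assert worse <= base


class TestScanAndPredict:
    def test_scan_equals_scalar_alignment_per_window(self):
        rng = np.random.default_rng(9)
        m = rand_rna(20, rng)
        t = rand_rna(300, rng)
        # plant a perfect site so at least one window qualifies
        t = t[:100] + revcomp_rna(m) + t[100 + 20:]
        w = len(m) + 3
        threshold = 24  # 12.0 in Allen units, generous to exercise both sides
        hits = set(scan_best_sites(m, t, threshold))
        for st in range(len(t) - w + 1):
            aln = align_duplex(m, t[st:st + w])
            assert (st in hits) == (aln.allen_score * 2 <= threshold)

    def test_embedded_perfect_site_reported(self):
        rng = np.random.default_rng(10)
        m = rand_rna(21, rng)
        t = rand_rna(400, rng)
        t = t[:250] + revcomp_rna(m) + t[250 + 21:]
        df = predict_targets({"miR": m}, {"tx": t})
        assert len(df) == 1
        row = df.iloc[0]
        assert row.allen_score == 0.0
        assert row.site_start <= 250 <= row.site_start + 3

    def test_random_background_yields_no_calls(self):
        rng = np.random.default_rng(11)
        mirnas = {f"miR{i}": rand_rna(21, rng) for i in range(3)}
        txs = {f"tx{i}": rand_rna(500, rng) for i in range(20)}
        df = predict_targets(mirnas, txs)
        assert len(df) == 0

    def test_short_transcripts_logged_as_skipped(self):
        m = rand_rna(21)
        df = predict_targets({"miR": m}, {"short": rand_rna(10)})
        assert df.attrs["skipped"] == [("miR", "short")]
        assert len(df) == 0

    def test_best_site_selected_before_thresholds(self):
        """A pair whose best (lowest-Allen) site fails the MFE filter is not
        rescued by a worse-Allen qualifying site elsewhere."""
        from saltnet.synthio import _apply_mismatch, _apply_wobble

        rng = np.random.default_rng(12)
        # G/U rich miRNA so wobble sites are constructible
        m = "GGUAGGUCAGGUUGAGGAACC"
        # site A: three core mismatches -> allen 6.0 but poor energy
        a = list(revcomp_rna(m))
        for pos in (4, 7, 10):
            _apply_mismatch(a, m, pos)
        site_a = "".join(a)
        aln_a = align_duplex(m, site_a)
        assert aln_a.allen_score == 6.0 and aln_a.mfe_ratio <= 0.65
        # site B: wobbles only -> allen in (6, 7], full pairing energy
        b = list(revcomp_rna(m))
        added = 0.0
        for pos in range(1, len(m) + 1):
            if added > 6.0:
                break
            if _apply_wobble(b, m, pos):
                added += 1.0 if 2 <= pos <= 13 else 0.5
        site_b = "".join(b)
        aln_b = align_duplex(m, site_b)
        assert 6.0 < aln_b.allen_score <= 7.0 and aln_b.mfe_ratio > 0.65
        pad = rand_rna(60, rng)
        tx = pad + site_a + rand_rna(60, rng) + site_b + pad
        # site B alone qualifies ...
        assert len(predict_targets({"miR": m}, {"t": pad + site_b + pad})) == 1
        # ... but with the lower-Allen failing site A present, the pair's
        # best site fails the MFE rule and the pair is not reported
        assert len(predict_targets({"miR": m}, {"t": tx})) == 0

    def test_report_all_sites_flag(self):
        rng = np.random.default_rng(13)
        m = rand_rna(21, rng)
        site = revcomp_rna(m)
        t = rand_rna(60, rng) + site + rand_rna(60, rng) + site + rand_rna(60, rng)
        one = predict_targets({"miR": m}, {"tx": t})
        both = predict_targets({"miR": m}, {"tx": t}, report_all_sites=True)
        assert len(one) == 1
        assert len(both) >= 2
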