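"""Candidate selection, greedy LD clumping (against an exhaustive reference
implementation), and allele harmonization with its provenance log."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from virtmet.instruments import (HarmonizedInstrument, harmonize,
                                 instrument_from_frames, ld_clump,
                                 select_candidates)
from virtmet.scores import InstrumentError


def _stats(rows):
    return pd.DataFrame(rows, columns=[
        "variant", "chrom", "pos", "effect_allele", "other_allele",
        "eaf", "beta", "se", "p", "n"])


def _row(variant, chrom="1", pos=100, ea="A", oa="G", eaf=0.3, beta=0.1,
         se=0.05, p=1e-7, n=1000):
    return dict(variant=variant, chrom=chrom, pos=pos, effect_allele=ea,
                other_allele=oa, eaf=eaf, beta=beta, se=se, p=p, n=n)


class TestSelect:
    def test_strict_threshold(self):
        df = _stats([_row("a", p=1e-7), _row("b", p=1e-5), _row("c", p=1e-3)])
        kept = select_candidates(df, 5e-6)
        assert list(kept["variant"]) == ["a"]

    def test_empty_result_allowed(self):
        df = _stats([_row("a", p=0.5)])
        assert select_candidates(df, 5e-6).empty

    def test_threshold_one_keeps_all(self):
        df = _stats([_row("a", p=0.9), _row("b", p=0.5)])
        assert len(select_candidates(df, 1.0)) == 2


def _reference_greedy(cand: pd.DataFrame, r2: pd.DataFrame, r2_thr: float,
                      window_bp: float) -> list[str]:
    """Exhaustive re-implementation of the greedy clump rule."""
    remaining = cand.sort_values(["p", "chrom", "pos"], kind="mergesort")
    remaining = list(remaining.itertuples())
    kept = []
    while remaining:
        index = remaining.pop(0)
        kept.append(index.variant)
        survivors = []
        for other in remaining:
            same_chr = other.chrom == index.chrom
            close = abs(other.pos - index.pos) <= window_bp
            linked = same_chr and close and r2.loc[index.variant, other.variant] >= r2_thr
            if not linked:
                survivors.append(other)
        remaining = survivors
    return kept


class TestClump:
    def test_high_ld_pair_keeps_best_p(self):
        cand = _stats([_row("a", pos=10_000, p=1e-8),
                       _row("b", pos=20_000, p=1e-7)])
        r2 = pd.DataFrame([[1.0, 0.9], [0.9, 1.0]], index=["a", "b"],
                          columns=["a", "b"])
        kept, log = ld_clump(cand, r2, 0.05, 1000.0)
        assert list(kept["variant"]) == ["a"]
        assert any(e["action"] == "clumped" and e["variant"] == "b" for e in log)

    def test_different_chromosomes_all_retained(self):
        cand = _stats([_row("a", chrom="1", pos=100, p=1e-8),
                       _row("b", chrom="2", pos=100, p=1e-7)])
        r2 = pd.DataFrame(np.eye(2), index=["a", "b"], columns=["a", "b"])
        kept, _ = ld_clump(cand, r2, 0.05, 1000.0)
        assert set(kept["variant"]) == {"a", "b"}

    def test_window_inclusive_at_exactly_window_kb(self):
        cand = _stats([_row("a", pos=1, p=1e-9),
                       _row("b", pos=1_000_001, p=1e-8),   # exactly 1000 kb
                       _row("c", pos=1_000_002, p=1e-7)])  # just past
        r2 = pd.DataFrame(np.ones((3, 3)), index=list("abc"), columns=list("abc"))
        kept, _ = ld_clump(cand, r2, 0.05, 1000.0)
        assert set(kept["variant"]) == {"a", "c"}

    def test_missing_ld_policies(self):
        cand = _stats([_row("a", pos=100, p=1e-8), _row("b", pos=200, p=1e-7)])
        r2 = pd.DataFrame([[1.0]], index=["a"], columns=["a"])
        kept_ind, log = ld_clump(cand, r2, 0.05, 1000.0, "assume_independent")
        assert set(kept_ind["variant"]) == {"a", "b"}
        kept_drop, _ = ld_clump(cand, r2, 0.05, 1000.0, "drop")
        assert set(kept_drop["variant"]) == {"a"}
        assert any(e["action"] == "missing_ld" for e in log)

    def test_matches_exhaustive_reference_on_random_instances(self):
        rng = np.random.default_rng(123)
        for _ in range(200):
            n = 10
            names = [f"v{i}" for i in range(n)]
            chrom = rng.choice(["1", "2"], n)
            pos = rng.integers(1, 3_000_000, n)
            cand = _stats([
                _row(names[i], chrom=chrom[i], pos=int(pos[i]),
                     p=float(rng.uniform(1e-10, 1e-5))) for i in range(n)])
            a = rng.uniform(size=(n, n))
            r2m = (a + a.T) / 2
            np.fill_diagonal(r2m, 1.0)
            r2 = pd.DataFrame(r2m, index=names, columns=names)
            kept, _ = ld_clump(cand, r2, 0.3, 500.0)
            ref = _reference_greedy(cand, r2, 0.3, 500_000.0)
            assert set(kept["variant"]) == set(ref)

    @settings(derandomize=True, max_examples=25)
    @given(st.randoms(use_true_random=False))
    def test_row_order_invariance(self, rnd):
        rng = np.random.default_rng(rnd.randrange(2 ** 31))
        n = 8
        names = [f"v{i}" for i in range(n)]
        cand = _stats([
            _row(names[i], chrom="1", pos=int(rng.integers(1, 2_000_000)),
                 p=float(rng.uniform(1e-10, 1e-5))) for i in range(n)])
        a = rng.uniform(size=(n, n))
        r2 = pd.DataFrame((a + a.T) / 2, index=names, columns=names)
        kept1, _ = ld_clump(cand, r2, 0.2, 800.0)
        shuffled = cand.sample(frac=1.0, random_state=rng.integers(1 << 16))
        kept2, _ = ld_clump(shuffled, r2, 0.2, 800.0)
        assert set(kept1["variant"]) == set(kept2["variant"])

    def test_retained_set_respects_r2_bound_on_panel(self, small_study):
        stats = small_study.exposure_stats["met000"]
        cand = select_candidates(stats, 5e-6)
        kept, _ = ld_clump(cand, small_study.panel, 0.05, 1000.0)
        vi = small_study.panel.variant_index()
        d = small_study.panel.dosages
        for i, a in enumerate(kept["variant"]):
            for b in kept["variant"][i + 1:]:
                pa, pb = kept.set_index("variant").loc[[a, b], "pos"]
                same = (kept.set_index("variant").loc[a, "chrom"]
                        == kept.set_index("variant").loc[b, "chrom"])
                if same and abs(pa - pb) <= 1_000_000:
                    r2 = np.corrcoef(d[:, vi[a]], d[:, vi[b]])[0, 1] ** 2
                    assert r2 < 0.05


class TestHarmonize:
    def test_effect_allele_swap_flips_sign(self):
        exp = _stats([_row("a", ea="A", oa="G", beta=0.1)])
        out = _stats([_row("a", ea="G", oa="A", beta=-0.2)])
        inst = harmonize(exp, out)
        assert inst.snps["beta_out"].iloc[0] == pytest.approx(0.2)
        assert any(e["action"] == "flip" for e in inst.provenance)

    def test_strand_complement_alignment(self):
        # exposure A/G; outcome reported as T/C (same variant, other strand)
        exp = _stats([_row("a", ea="A", oa="G", beta=0.1)])
        out = _stats([_row("a", ea="T", oa="C", beta=0.3)])
        inst = harmonize(exp, out)
        assert inst.snps["beta_out"].iloc[0] == pytest.approx(0.3)
        assert any(e["action"] == "complement" for e in inst.provenance)

    def test_allele_mismatch_dropped(self):
        exp = _stats([_row("a", ea="A", oa="G"), _row("b", pos=200, ea="A", oa="G")])
        out = _stats([_row("a", ea="A", oa="C"), _row("b", pos=200, ea="A", oa="G")])
        inst = harmonize(exp, out)
        assert list(inst.snps["variant"]) == ["b"]
        assert any(e["reason"] == "allele_mismatch" for e in inst.provenance)

    def test_ambiguous_palindrome_dropped(self):
        exp = _stats([_row("a", ea="A", oa="T", eaf=0.50),
                      _row("b", pos=200, ea="A", oa="G")])
        out = _stats([_row("a", ea="A", oa="T", eaf=0.50),
                      _row("b", pos=200, ea="A", oa="G")])
        inst = harmonize(exp, out)
        assert list(inst.snps["variant"]) == ["b"]
        assert any(e["reason"] == "palindromic_ambiguous_frequency"
                   for e in inst.provenance)

    def test_informative_palindrome_aligned_by_frequency(self):
        exp = _stats([_row("a", ea="A", oa="T", eaf=0.1, beta=0.5)])
        out = _stats([_row("a", ea="A", oa="T", eaf=0.9, beta=0.2)])
        inst = harmonize(exp, out)
        # frequencies disagree -> outcome effect allele is the complementary
        # strand's label for the other allele: flip
        assert inst.snps["beta_out"].iloc[0] == pytest.approx(-0.2)

    def test_zero_survivors_raise(self):
        exp = _stats([_row("a", ea="A", oa="G")])
        out = _stats([_row("a", ea="A", oa="C")])
        with pytest.raises(InstrumentError):
            harmonize(exp, out)

    def test_involution_safe(self):
        rng = np.random.default_rng(9)
        exp = _stats([
            _row(f"v{i}", chrom="1", pos=1000 * (i + 1),
                 ea=["A", "G"][i % 2], oa=["G", "A"][i % 2],
                 eaf=float(rng.uniform(0.1, 0.4)),
                 beta=float(rng.normal()), se=0.05) for i in range(6)])
        out = exp.copy()
        flip = out.index % 2 == 1
        out.loc[flip, ["effect_allele", "other_allele"]] = \
            out.loc[flip, ["other_allele", "effect_allele"]].to_numpy()
        out.loc[flip, "beta"] = -out.loc[flip, "beta"]
        out.loc[flip, "eaf"] = 1 - out.loc[flip, "eaf"]
        once = harmonize(exp, out)
        # re-harmonize the already-aligned outcome against the same exposure
        realigned = once.snps.rename(columns={
            "beta_out": "beta", "se_out": "se", "eaf_out": "eaf"})
        twice = harmonize(exp, realigned.assign(n=1000))
        assert np.allclose(once.snps["beta_out"], twice.snps["beta_out"])

    def test_end_to_end_builder(self, small_study):
        stats = small_study.exposure_stats["met000"]
        outcome = small_study.replication_stats(list(stats["variant"]))
        inst = instrument_from_frames(
            "met000", "574.1", stats, outcome, small_study.panel)
        assert inst.n_snps >= 3
        assert isinstance(inst, HarmonizedInstrument)
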