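"""Informative-SNP classification, phasing, key marking, voting, verdicts."""

import itertools

import numpy as np
import pandas as pd
import pytest

from cellhap import (
    DiseaseLocus,
    Genotype,
    HaplotypeCall,
    PhasingError,
    SimulationConfig,
    call_fetal_haplotype,
    classify_informative_snps,
    derive_verdict,
    mark_key_snps,
    merge_tables,
    observe_single_cell,
    phase_to_pathogenic,
    simulate_family,
)
from _util import make_table

G = Genotype

AR_LOCUS = DiseaseLocus(
    gene_name="GENE_A",
    chrom="chr7",
    position=5_000,
    inheritance_mode="autosomal_recessive",
    carrier_parents=("father", "mother"),
    pathogenic_positions={"father": 4_000, "mother": 6_000},
)


def _trio_table(father, mother, proband, cell=None, pos=None):
    samples = {"FATHER": father, "MOTHER": mother, "PROBAND": proband}
    if cell is not None:
        samples["CELL"] = cell
    return make_table(samples, pos=pos)


class TestInformativeClassification:
    def test_origin_rules(self):
        table = _trio_table(
            father=[G.HET, G.HET, G.HOM_REF, G.HET, G.HOM_REF],
            mother=[G.HOM_REF, G.HET, G.HET, G.HOM_ALT, G.HOM_REF],
            proband=[G.HOM_REF, G.HET, G.HET, G.HET, G.HOM_REF],
            pos=[1000, 2000, 3000, 7000, 8000],
        )
        inf = classify_informative_snps(table, AR_LOCUS, flank=10_000)
        assert list(inf["pos"]) == [1000, 3000, 7000]
        assert list(inf["origin"]) == ["IFF", "IFM", "IFF"]
        # father 0/1, mother 0/1 at pos 2000 -> excluded (other parent not hom);
        # both hom at 8000 -> uninformative

    def test_transmitted_allele_by_subtraction(self):
        # IFM site: father 0/0 obliges a ref allele, proband 0/1 -> mother gave ALT
        table = _trio_table(
            father=[G.HOM_REF], mother=[G.HET], proband=[G.HET], pos=[1000]
        )
        inf = classify_informative_snps(table, AR_LOCUS, flank=10_000)
        assert inf.iloc[0]["origin"] == "IFM"
        assert inf.iloc[0]["proband_allele"] == 1

    def test_inconsistent_or_missing_proband_excluded(self):
        table = _trio_table(
            father=[G.HET, G.HET],
            mother=[G.HOM_REF, G.HOM_REF],
            proband=[G.HOM_ALT, G.MISSING],  # 1/1 impossible given mother 0/0
            pos=[1000, 2000],
        )
        assert len(classify_informative_snps(table, AR_LOCUS, flank=10_000)) == 0

    def test_window_and_anchor_exclusion(self):
        table = _trio_table(
            father=[G.HET] * 3,
            mother=[G.HOM_REF] * 3,
            proband=[G.HET] * 3,
            pos=[4_000, 5_500, 50_000],  # pathogenic site, in-window, out of window
        )
        inf = classify_informative_snps(table, AR_LOCUS, flank=10_000)
        assert list(inf["pos"]) == [5_500]
        assert inf.iloc[0]["distance"] == 500

    def test_haploid_proband_uses_mother_only(self):
        locus = DiseaseLocus(
            gene_name="F9", chrom="chrX", position=5_000,
            inheritance_mode="x_linked", carrier_parents=("mother",),
        )
        table = make_table(
            {
                "FATHER": [G.HEM_REF, G.HEM_ALT, G.HEM_REF],
                "MOTHER": [G.HET, G.HET, G.HOM_REF],
                "PROBAND": [G.HEM_ALT, G.HEM_REF, G.HEM_REF],
            },
            pos=[1000, 2000, 3000],
            chrom="chrX",
            haploid={"FATHER": True, "PROBAND": True},
        )
        inf = classify_informative_snps(table, locus, flank=10_000)
        # the father's hemizygous genotype places no constraint on a male proband
        assert list(inf["pos"]) == [1000, 2000]
        assert list(inf["origin"]) == ["IFM", "IFM"]
        assert list(inf["proband_allele"]) == [1, 0]


class TestPhasing:
    def test_phased_alleles_match_truth_haplotype_one(self):
        cfg = SimulationConfig(
            n_snps=200, mean_depth=60, ado_rate=0.0, fp_rate=0.0,
            crossover_prob=0.0, seed=13,
        )
        truth = simulate_family(cfg)
        fam = merge_tables(
            truth.to_genotype_table(include_reference=True),
            observe_single_cell(truth),
        )
        inf = classify_informative_snps(fam, truth.locus)
        pos2i = {int(p): i for i, p in enumerate(fam.sites["pos"])}
        for parent, hap, origin in (
            ("father", truth.paternal_haplotypes, "IFF"),
            ("mother", truth.maternal_haplotypes, "IFM"),
        ):
            phased = phase_to_pathogenic(inf, fam, truth.locus, parent)
            sub = phased[(phased["origin"] == origin) & phased["hap1_allele"].notna()]
            idx = [pos2i[int(p)] for p in sub["pos"]]
            np.testing.assert_array_equal(
                sub["hap1_allele"].astype(int).values, hap[0, idx]
            )

    def test_proband_without_pathogenic_allele_flips_assignment(self):
        # mother carrier het at 6000; proband 0/0 there -> did not inherit M1,
        # so the allele the mother transmitted elsewhere sits on M2
        table = _trio_table(
            father=[G.HOM_REF, G.HOM_REF],
            mother=[G.HET, G.HET],
            proband=[G.HET, G.HOM_REF],
            pos=[5_500, 6_000],
        )
        phased = phase_to_pathogenic(
            classify_informative_snps(table, AR_LOCUS, flank=10_000),
            table, AR_LOCUS, "mother",
        )
        row = phased[phased["pos"] == 5_500].iloc[0]
        # mother transmitted ALT to the proband, but that's haplotype 2;
        # haplotype 1 carries the complement
        assert row["proband_allele"] == 1
        assert row["hap1_allele"] == 0

    def test_missing_proband_at_locus_raises(self):
        table = _trio_table(
            father=[G.HOM_REF, G.HOM_REF],
            mother=[G.HET, G.HET],
            proband=[G.HET, G.MISSING],
            pos=[5_500, 6_000],
        )
        inf = classify_informative_snps(table, AR_LOCUS, flank=10_000)
        with pytest.raises(PhasingError, match="missing or inconsistent"):
            phase_to_pathogenic(inf, table, AR_LOCUS, "mother")

    def test_non_carrier_parent_rejected(self):
        locus = DiseaseLocus(
            gene_name="G", chrom="chr7", position=5_000,
            inheritance_mode="autosomal_dominant", carrier_parents=("father",),
        )
        table = _trio_table(
            father=[G.HET], mother=[G.HOM_REF], proband=[G.HET], pos=[5_000]
        )
        inf = classify_informative_snps(table, locus, flank=10_000)
        with pytest.raises(PhasingError, match="not a carrier"):
            phase_to_pathogenic(inf, table, locus, "mother")


def _single_dropout_observations(true_alleles):
    """All genotypes producible from a true allele multiset by <=1 dropout.

    Dropping both alleles gives a missing site, which carries no signal;
    the caller of this oracle treats missing as uninformative.
    """
    outcomes = set()
    a, b = true_alleles
    outcomes.add(frozenset({(a, 1 if a == b else None)}))  # placeholder, replaced below
    outcomes = set()
    # no dropout
    outcomes.add(tuple(sorted((a, b))))
    # drop one allele -> hemizygous amplification of the other, observed hom
    outcomes.add((a, a))
    outcomes.add((b, b))
    return outcomes


def _code_from_pair(pair):
    return {(0, 0): G.HOM_REF, (0, 1): G.HET, (1, 1): G.HOM_ALT}[tuple(sorted(pair))]


class TestKeyMarking:
    @pytest.mark.parametrize("other_allele", [0, 1])
    @pytest.mark.parametrize(
        "cell_code", [G.HOM_REF, G.HET, G.HOM_ALT, G.MISSING]
    )
    def test_matches_dropout_enumeration_oracle(self, other_allele, cell_code):
        """A site is key iff the observation is consistent with exactly one
        transmission hypothesis under the <=1-dropout model."""
        a = other_allele
        consistent = set()
        for h in (0, 1):  # hypothesis: informative parent transmitted h
            if cell_code == G.MISSING:
                consistent.add(h)  # missing is consistent with anything
                continue
            observed = tuple(sorted(genotype_pair(cell_code)))
            if observed in _single_dropout_observations((a, h)):
                consistent.add(h)
        oracle_key = len(consistent) == 1 and cell_code != G.MISSING

        table = _trio_table(
            father=[G.HET], mother=[G.HOM_REF if a == 0 else G.HOM_ALT],
            proband=[G.HET if a == 0 else _code_from_pair((a, 1 - a))],
            cell=[cell_code], pos=[5_500],
        )
        inf = classify_informative_snps(table, AR_LOCUS, flank=10_000)
        marked = mark_key_snps(inf, table)
        assert bool(marked.iloc[0]["key"]) == oracle_key
        if oracle_key:
            assert int(marked.iloc[0]["cell_allele"]) == consistent.pop()

    def test_missing_cell_is_non_key(self):
        table = _trio_table(
            father=[G.HET], mother=[G.HOM_REF], proband=[G.HET],
            cell=[G.MISSING], pos=[5_500],
        )
        inf = mark_key_snps(
            classify_informative_snps(table, AR_LOCUS, flank=10_000), table
        )
        assert not inf.iloc[0]["key"]

    def test_trio_mode_votes_every_called_site(self):
        table = _trio_table(
            father=[G.HET, G.HET], mother=[G.HOM_REF, G.HOM_REF],
            proband=[G.HET, G.HET], cell=[G.HOM_REF, G.MISSING],
            pos=[5_500, 5_600],
        )
        inf = classify_informative_snps(table, AR_LOCUS, flank=10_000)
        marked = mark_key_snps(inf, table, mode="trio")
        assert list(marked["key"]) == [True, False]
        # the shared-allele homozygote votes for shared-allele transmission
        assert marked.iloc[0]["cell_allele"] == 0

    def test_hemizygous_cell_every_call_is_key(self):
        locus = DiseaseLocus(
            gene_name="F9", chrom="chrX", position=5_000,
            inheritance_mode="x_linked", carrier_parents=("mother",),
        )
        table = make_table(
            {
                "FATHER": [G.HEM_REF] * 3,
                "MOTHER": [G.HET] * 3,
                "PROBAND": [G.HEM_ALT] * 3,
                "CELL": [G.HEM_REF, G.HEM_ALT, G.MISSING],
            },
            pos=[1000, 2000, 3000], chrom="chrX",
            haploid={"FATHER": True, "PROBAND": True, "CELL": True},
        )
        inf = mark_key_snps(classify_informative_snps(table, locus, flank=10_000), table)
        assert list(inf["key"]) == [True, True, False]
        assert list(inf["cell_allele"].astype("Int64"))[:2] == [0, 1]


def genotype_pair(code):
    return {G.HOM_REF: (0, 0), G.HET: (0, 1), G.HOM_ALT: (1, 1)}[code]


def _phased_frame(up_votes, down_votes, origin="IFF"):
    """Key-SNP frame with given (for-1, for-2) votes per flank."""
    rows = []
    pos = 1000
    for flank_sign, (n1, n2) in ((-1, up_votes), (1, down_votes)):
        for vote1 in [True] * n1 + [False] * n2:
            rows.append(
                dict(
                    chrom="chr7", pos=pos, ref="A", alt="G", origin=origin,
                    other_allele=0, proband_allele=1,
                    distance=flank_sign * pos, hap1_allele=1,
                    key=True, cell_allele=1 if vote1 else 0,
                )
            )
            pos += 10
    df = pd.DataFrame(rows)
    df["hap1_allele"] = df["hap1_allele"].astype("Int64")
    df["cell_allele"] = df["cell_allele"].astype("Int64")
    return df


class TestVoting:
    def test_unanimous_flanks_vote_counts_reported(self):
        call = call_fetal_haplotype(_phased_frame((10, 0), (3, 0)), "father")
        assert call.label == 1
        assert call.upstream_votes == (10, 0)
        assert call.downstream_votes == (3, 0)
        assert not call.recombination_flag

    def test_discordant_flanks_flag_recombination(self):
        call = call_fetal_haplotype(_phased_frame((6, 0), (0, 5)), "father")
        assert call.label is None
        assert call.recombination_flag
        assert "discordance" in call.message

    def test_empty_flank_is_ambiguous_with_diagnostic(self):
        call = call_fetal_haplotype(_phased_frame((4, 0), (0, 0)), "father")
        assert call.label is None
        assert "downstream" in call.message

    def test_sub_threshold_majority_abstains(self):
        # 7/3 = 0.7 < 0.8 threshold
        call = call_fetal_haplotype(_phased_frame((7, 3), (5, 0)), "father")
        assert call.label is None
        call2 = call_fetal_haplotype(
            _phased_frame((7, 3), (5, 0)), "father", vote_threshold=0.7
        )
        assert call2.label == 1

    def test_min_key_snps_requirement(self):
        call = call_fetal_haplotype(
            _phased_frame((3, 0), (2, 0)), "father", min_key_snps=5
        )
        assert call.label is None

    def test_label_symmetry_under_haplotype_relabelling(self):
        """Swapping which physical haplotype is pathogenic flips the label
        and swaps the per-flank vote pairs."""
        df = _phased_frame((8, 1), (5, 1))
        call = call_fetal_haplotype(df, "father")
        flipped = df.copy()
        flipped["hap1_allele"] = 1 - flipped["hap1_allele"].astype(int)
        flipped["hap1_allele"] = flipped["hap1_allele"].astype("Int64")
        call_f = call_fetal_haplotype(flipped, "father")
        assert call.label == 1 and call_f.label == 2
        assert call_f.upstream_votes == call.upstream_votes[::-1]
        assert call_f.downstream_votes == call.downstream_votes[::-1]


class TestVerdict:
    def _call(self, parent, label, ambiguous=False):
        return HaplotypeCall(
            parent=parent,
            label=None if ambiguous else label,
            upstream_votes=(3, 0),
            downstream_votes=(3, 0),
        )

    @pytest.mark.parametrize(
        "pat, mat, expected",
        [
            (1, 1, "affected"),
            (1, 2, "carrier_paternal"),
            (2, 1, "carrier_maternal"),
            (2, 2, "normal"),
        ],
    )
    def test_autosomal_recessive_truth_table(self, pat, mat, expected):
        locus = DiseaseLocus(
            gene_name="G", chrom="chr7", position=1,
            inheritance_mode="autosomal_recessive",
        )
        v = derive_verdict(
            self._call("father", pat), self._call("mother", mat), locus
        )
        assert v.value == expected

    @pytest.mark.parametrize(
        "sex, label, expected",
        [("male", 1, "affected"), ("male", 2, "normal"),
         ("female", 1, "carrier_maternal"), ("female", 2, "normal")],
    )
    def test_x_linked(self, sex, label, expected):
        locus = DiseaseLocus(
            gene_name="F9", chrom="chrX", position=1,
            inheritance_mode="x_linked", carrier_parents=("mother",),
        )
        v = derive_verdict(None, self._call("mother", label), locus, fetal_sex=sex)
        assert v.value == expected

    @pytest.mark.parametrize("label, expected", [(1, "affected"), (2, "normal")])
    def test_autosomal_dominant_single_carrier(self, label, expected):
        locus = DiseaseLocus(
            gene_name="G", chrom="chr7", position=1,
            inheritance_mode="autosomal_dominant", carrier_parents=("father",),
        )
        v = derive_verdict(self._call("father", label), None, locus)
        assert v.value == expected

    def test_ambiguous_input_propagates(self):
        locus = DiseaseLocus(
            gene_name="G", chrom="chr7", position=1,
            inheritance_mode="autosomal_recessive",
        )
        v = derive_verdict(
            self._call("father", 1, ambiguous=True), self._call("mother", 1), locus
        )
        assert v.value == "ambiguous"

    def test_missing_required_call_raises(self):
        locus = DiseaseLocus(
            gene_name="G", chrom="chr7", position=1,
            inheritance_mode="autosomal_recessive",
        )
        with pytest.raises(ValueError, match="missing required"):
            derive_verdict(self._call("father", 1), None, locus)


class TestNoiseFreeCompleteness:
    def test_transmitted_distinguishing_alleles_all_key_and_unanimous(
        self, clean_truth, clean_family
    ):
        inf = classify_informative_snps(clean_family, clean_truth.locus)
        for parent in ("father", "mother"):
            inf = phase_to_pathogenic(inf, clean_family, clean_truth.locus, parent)
        inf = mark_key_snps(inf, clean_family)
        pos2i = {int(p): i for i, p in enumerate(clean_family.sites["pos"])}
        called = clean_family.gt("CELL") != int(G.MISSING)
        for parent, hap, origin, tkey in (
            ("father", clean_truth.paternal_haplotypes, "IFF", "paternal"),
            ("mother", clean_truth.maternal_haplotypes, "IFM", "maternal"),
        ):
            trans = clean_truth.fetal_transmissions[tkey]
            sub = inf[inf["origin"] == origin]
            idx = np.asarray([pos2i[int(p)] for p in sub["pos"]])
            b = 1 - sub["other_allele"].values
            transmitted = np.where(trans[idx] == 1, hap[0, idx], hap[1, idx])
            should_be_key = (transmitted == b) & called[idx]
            assert (sub["key"].values == should_be_key).all()
            call = call_fetal_haplotype(inf, parent)
            truth_label = int(trans[0])  # no crossover: constant
            assert call.label == truth_label
            assert call.upstream_votes[2 - truth_label] == 0
            assert call.downstream_votes[2 - truth_label] == 0


def _exhaustive_oracle(rows, cell_codes):
    """Decide the transmitted haplotype by enumerating both window-wide
    transmission hypotheses x per-site <=1-dropout patterns.

    Each row is (other_allele, hap1_allele); hypothesis H in {1, 2} means
    every site transmitted its haplotype-H allele.  A hypothesis is
    consistent when every observed cell genotype can be produced from the
    implied true genotype by dropping at most one allele (missing sites
    are always producible via double dropout).  Returns 1, 2 or None.
    """
    consistent = []
    for hyp in (1, 2):
        ok = True
        for (a, h1), code in zip(rows, cell_codes):
            t = h1 if hyp == 1 else 1 - h1
            if code == G.MISSING:
                continue
            observed = tuple(sorted(genotype_pair(code)))
            if observed not in _single_dropout_observations((a, t)):
                ok = False
                break
        if ok:
            consistent.append(hyp)
    return consistent[0] if len(consistent) == 1 else None


class TestOracleEquivalence:
    def test_voting_agrees_with_exhaustive_oracle(self):
        """On small random instances the flank-voting call never contradicts
        the hypothesis x dropout-pattern enumeration."""
        rng = np.random.default_rng(99)
        n_decisive = n_called = 0
        for _ in range(300):
            n_snps = int(rng.integers(2, 13))
            rows, codes, frame_rows = [], [], []
            for j in range(n_snps):
                a = int(rng.integers(0, 2))
                h1 = int(rng.integers(0, 2))
                true_t = h1 if rng.random() < 0.5 else 1 - h1
                pair = sorted((a, true_t))
                # apply dropout / missingness to the observation
                u = rng.random()
                if u < 0.15:
                    code = G.MISSING
                elif u < 0.45:
                    keep = pair[int(rng.integers(0, 2))]
                    code = _code_from_pair((keep, keep))
                else:
                    code = _code_from_pair(pair)
                rows.append((a, h1))
                codes.append(code)
                distance = (j - n_snps / 2) * 100 or -50
                frame_rows.append(
                    dict(
                        chrom="chr7", pos=1000 + j, ref="A", alt="G",
                        origin="IFF", other_allele=a, proband_allele=h1,
                        distance=distance, hap1_allele=h1,
                        key=False, cell_allele=pd.NA,
                    )
                )
            oracle = _exhaustive_oracle(rows, codes)
            frame = pd.DataFrame(frame_rows)
            frame["hap1_allele"] = frame["hap1_allele"].astype("Int64")
            table = make_table({"CELL": codes}, pos=list(1000 + np.arange(n_snps)))
            marked = mark_key_snps(frame, table)
            call = call_fetal_haplotype(marked, "father", vote_threshold=0.8)
            if oracle is not None:
                n_decisive += 1
                if call.label is not None:
                    n_called += 1
                    assert call.label == oracle
        assert n_decisive > 100
        assert n_called > 0.3 * n_decisive


class TestRecoveryUnderNoise:
    def test_unambiguous_calls_match_truth(self):
        """Under moderate WGA noise nearly all unambiguous calls recover the
        planted fetal transmission; flank discordance is never miscalled."""
        from cellhap import FetalHaplotypeModel

        n_correct = n_unambiguous = 0
        for seed in range(40):
            cfg = SimulationConfig(
                n_snps=400, mean_depth=40, ado_rate=0.1, fp_rate=0.03, seed=seed
            )
            truth = simulate_family(cfg)
            fam = merge_tables(
                truth.to_genotype_table(include_reference=True),
                observe_single_cell(truth),
            )
            results = FetalHaplotypeModel(fam, truth.locus).fit()
            for parent, tkey in (("father", "paternal"), ("mother", "maternal")):
                call = results.calls[parent]
                if call.label is None:
                    continue
                i = truth.site_index_of(
                    truth.locus.pathogenic_positions[parent]
                )
                n_unambiguous += 1
                n_correct += call.label == int(
                    truth.fetal_transmissions[tkey][i]
                )
        assert n_unambiguous >= 40
        assert n_correct / n_unambiguous >= 0.97

    def test_noise_degrades_monotonically_at_the_corners(self):
        """Error + ambiguity under heavy noise is at least that of the
        noise-free corner (sparse windows make ambiguity visible)."""

        def rate(d, e):
            bad = total = 0
            for seed in range(30):
                cfg = SimulationConfig(
                    n_snps=60, mean_depth=15, ado_rate=d, fp_rate=e, seed=seed
                )
                truth = simulate_family(cfg)
                fam = merge_tables(
                    truth.to_genotype_table(include_reference=True),
                    observe_single_cell(truth),
                )
                from cellhap import FetalHaplotypeModel

                results = FetalHaplotypeModel(fam, truth.locus).fit()
                for parent, tkey in (("father", "paternal"), ("mother", "maternal")):
                    call = results.calls[parent]
                    i = truth.site_index_of(
                        truth.locus.pathogenic_positions[parent]
                    )
                    want = int(truth.fetal_transmissions[tkey][i])
                    total += 1
                    bad += (call.label is None) or (call.label != want)
            return bad / total

        assert rate(0.25, 0.05) >= rate(0.0, 0.0)
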