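import pytest

from dsog import (
    DomainPair,
    DsoCall,
    Flag,
    Klass,
    RunConfig,
    build_presence_matrix,
    filter1_conservation,
    filter2_classify,
    filter6_genomic_check,
    filters3to5,
    reference_rules,
    run_cascade,
)
from dsog.pairs import species_domain_sets

from .conftest import make_hit

GNATHOSTOMES = ["ghost_shark", "zebrafish", "fugu", "frog", "chicken",
                "human", "mouse", "rat"]
PAIR = DomainPair("PF00051", "PF00594")


def hits_for_carriers(tree22, carriers, pair=PAIR, cov=0.9):
    data = {s: [] for s in tree22.leaves}
    for sp in carriers:
        gene = f"{sp}_g"
        data[sp].append(make_hit(sp, gene, pair.acc_a, 10, 100, cov=cov))
        data[sp].append(make_hit(sp, gene, pair.acc_b, 200, 300, cov=cov))
    return data


def single_domain_hits(data, species, acc, cov=0.9, gene=None):
    data[species].append(
        make_hit(species, gene or f"{species}_single_{acc}", acc, 400, 500, cov=cov))


class TestFilter1:
    def test_vertebrate_pair_needs_all_gnathostomes_plus_a_cyclostome(self, tree22):
        rules = reference_rules(tree22)
        data = hits_for_carriers(tree22, GNATHOSTOMES + ["arctic_lamprey"])
        m = build_presence_matrix(data)
        assert filter1_conservation(m, PAIR, rules["vertebrates"])

    def test_seven_of_eight_gnathostomes_fails(self, tree22):
        rules = reference_rules(tree22)
        data = hits_for_carriers(tree22, GNATHOSTOMES[:-1] + ["arctic_lamprey"])
        m = build_presence_matrix(data)
        assert not filter1_conservation(m, PAIR, rules["vertebrates"])

    def test_cyclostome_pair_needs_both_lamprey_and_hagfish(self, tree22):
        rules = reference_rules(tree22)
        m = build_presence_matrix(
            hits_for_carriers(tree22, ["arctic_lamprey", "sea_lamprey"]))
        assert not filter1_conservation(m, PAIR, rules["cyclostomes"])
        m = build_presence_matrix(
            hits_for_carriers(tree22, ["arctic_lamprey", "hagfish"]))
        assert filter1_conservation(m, PAIR, rules["cyclostomes"])


class TestFilter2:
    def test_both_domains_in_outgroup_is_class2(self, tree22):
        rules = reference_rules(tree22)
        data = hits_for_carriers(tree22, ["arctic_lamprey", "human"])
        single_domain_hits(data, "amphioxus", PAIR.acc_a)
        single_domain_hits(data, "amphioxus", PAIR.acc_b)
        klass = filter2_classify(
            species_domain_sets(data), PAIR, rules["vertebrates"])
        assert klass is Klass.CLASS2

    def test_lineage_restricted_domain_is_class1(self, tree22):
        rules = reference_rules(tree22)
        data = hits_for_carriers(tree22, ["arctic_lamprey", "human"])
        single_domain_hits(data, "amphioxus", PAIR.acc_a)  # acc_b nowhere outside
        klass = filter2_classify(
            species_domain_sets(data), PAIR, rules["vertebrates"])
        assert klass is Klass.CLASS1

    def test_no_outgroup_occurrence_is_class1(self, tree22):
        rules = reference_rules(tree22)
        data = hits_for_carriers(tree22, ["arctic_lamprey", "human"])
        klass = filter2_classify(
            species_domain_sets(data), PAIR, rules["vertebrates"])
        assert klass is Klass.CLASS1


def fresh_call(data, tree22, clade="vertebrates"):
    rules = reference_rules(tree22)
    return DsoCall(
        pair=PAIR, clade=clade, conserved=True, klass=Klass.CLASS2,
        filter_flags={"F1": Flag.PASS, "F2": Flag.PASS},
        genes={s: frozenset(h.gene_id for h in hits if h.pfam_acc in PAIR.accessions)
               for s, hits in data.items()
               if s in rules[clade].clade_species and hits},
    ), rules[clade]


class TestFilters3to5:
    def test_relaxed_outgroup_architecture_fails_f3(self, tree22):
        data = hits_for_carriers(tree22, GNATHOSTOMES + ["arctic_lamprey"])
        single_domain_hits(data, "amphioxus", PAIR.acc_a)
        single_domain_hits(data, "amphioxus", PAIR.acc_b)
        # planted boundary hit: both domains on one amphioxus gene at E=5e-2
        raw = {s: list(h) for s, h in data.items()}
        raw["amphioxus"] = raw["amphioxus"] + [
            make_hit("amphioxus", "amph_boundary", PAIR.acc_a, 10, 100, evalue=5e-2),
            make_hit("amphioxus", "amph_boundary", PAIR.acc_b, 200, 300, evalue=5e-2),
        ]
        call, rule = fresh_call(data, tree22)
        call = filters3to5(call, data, RunConfig(), rule, raw_hits=raw)
        assert call.filter_flags["F3"] is Flag.FAIL
        assert not call.is_dso

    def test_all_truncated_focal_instances_fail_f4(self, tree22):
        data = hits_for_carriers(tree22, GNATHOSTOMES + ["arctic_lamprey"], cov=0.3)
        single_domain_hits(data, "amphioxus", PAIR.acc_a)
        single_domain_hits(data, "amphioxus", PAIR.acc_b)
        call, rule = fresh_call(data, tree22)
        call = filters3to5(call, data, RunConfig(), rule)
        assert call.filter_flags["F4"] is Flag.FAIL

    def test_truncated_outgroup_evidence_reverts_to_class1_f5(self, tree22):
        data = hits_for_carriers(tree22, GNATHOSTOMES + ["arctic_lamprey"])
        single_domain_hits(data, "amphioxus", PAIR.acc_a, cov=0.2)  # truncated only
        single_domain_hits(data, "amphioxus", PAIR.acc_b)
        call, rule = fresh_call(data, tree22)
        call = filters3to5(call, data, RunConfig(), rule)
        assert call.filter_flags["F5"] is Flag.FAIL
        assert call.klass is Klass.CLASS1

    def test_disabled_predicates_are_skipped(self, tree22):
        data = hits_for_carriers(tree22, GNATHOSTOMES + ["arctic_lamprey"], cov=0.3)
        call, rule = fresh_call(data, tree22)
        cfg = RunConfig(enable_filter3=False, enable_filter4=False,
                        enable_filter5=False)
        call = filters3to5(call, data, cfg, rule)
        assert all(call.filter_flags[f] is Flag.SKIPPED for f in ("F3", "F4", "F5"))
        assert call.is_dso  # decided by Filters 1-2 only


class _HitEverything:
    def find_region(self, pair, gene_id, target_species):
        return True


class _HitNothing:
    def find_region(self, pair, gene_id, target_species):
        return False


class _Broken:
    def find_region(self, pair, gene_id, target_species):
        raise RuntimeError("backend down")


class TestFilter6:
    def _call(self):
        return DsoCall(
            pair=PAIR, clade="gnathostomes", conserved=True, klass=Klass.CLASS2,
            filter_flags={}, genes={"human": frozenset({"hg"})},
        )

    def test_hit_in_target_genome_fails(self):
        call = filter6_genomic_check(self._call(), _HitEverything(), ["hagfish"])
        assert call.filter_flags["F6"] is Flag.FAIL

    def test_no_hit_passes(self):
        call = filter6_genomic_check(self._call(), _HitNothing(), ["hagfish"])
        assert call.filter_flags["F6"] is Flag.PASS

    def test_no_backend_skips(self):
        call = filter6_genomic_check(self._call(), None, ["hagfish"])
        assert call.filter_flags["F6"] is Flag.SKIPPED

    def test_raising_backend_skips_with_warning_never_passes(self):
        with pytest.warns(UserWarning, match="backend failed"):
            call = filter6_genomic_check(self._call(), _Broken(), ["hagfish"])
        assert call.filter_flags["F6"] is Flag.SKIPPED


class TestCascade:
    def _run(self, data, tree22, **kwargs):
        rules = reference_rules(tree22)
        m = build_presence_matrix(data)
        return run_cascade(m, rules, data, RunConfig(), **kwargs)

    def outgroup_singles(self, data):
        single_domain_hits(data, "amphioxus", PAIR.acc_a)
        single_domain_hits(data, "amphioxus", PAIR.acc_b)

    def test_planted_vertebrate_pair_is_called(self, tree22):
        data = hits_for_carriers(tree22, GNATHOSTOMES + ["arctic_lamprey"])
        self.outgroup_singles(data)
        calls, manifest = self._run(data, tree22)
        dso = [c for c in calls if c.is_dso]
        assert [(c.pair, c.clade) for c in dso] == [(PAIR, "vertebrates")]
        assert manifest["clades"]["vertebrates"]["dso_dp"] == 1

    def test_pair_also_in_outgroup_yields_no_call(self, tree22):
        data = hits_for_carriers(
            tree22, GNATHOSTOMES + ["arctic_lamprey", "amphioxus"])
        calls, _ = self._run(data, tree22)
        assert [c for c in calls if c.clade == "vertebrates"] == []

    def test_class1_pair_not_dso(self, tree22):
        data = hits_for_carriers(tree22, GNATHOSTOMES + ["arctic_lamprey"])
        # domains absent from every outgroup species -> Class 1
        calls, _ = self._run(data, tree22)
        (call,) = [c for c in calls if c.clade == "vertebrates"]
        assert call.klass is Klass.CLASS1 and not call.is_dso

    def test_monotone_cascade(self, tree22):
        """Each filter only removes: survivors after k+1 filters <= after k."""
        data = hits_for_carriers(tree22, GNATHOSTOMES + ["arctic_lamprey"])
        self.outgroup_singles(data)
        extra = DomainPair("PF07000", "PF07001")
        for sp in GNATHOSTOMES[:4] + ["sea_lamprey"]:
            g = f"{sp}_e"
            data[sp].append(make_hit(sp, g, extra.acc_a, 10, 100))
            data[sp].append(make_hit(sp, g, extra.acc_b, 200, 300))
        calls, _ = self._run(data, tree22)
        stages = [
            lambda c: True,
            lambda c: c.filter_flags["F1"] is not Flag.FAIL,
            lambda c: c.filter_flags["F2"] is not Flag.FAIL,
            lambda c: c.filter_flags.get("F3") is not Flag.FAIL,
            lambda c: c.filter_flags.get("F4") is not Flag.FAIL,
            lambda c: c.filter_flags.get("F5") is not Flag.FAIL,
            lambda c: c.is_dso,
        ]
        surviving = set(range(len(calls)))
        for keep_upto in range(len(stages)):
            now = {
                i for i, c in enumerate(calls)
                if all(stages[k](c) for k in range(keep_upto + 1))
            }
            assert now <= surviving
            surviving = now

    def test_gnathostome_candidate_goes_through_filter6(self, tree22):
        data = hits_for_carriers(tree22, GNATHOSTOMES)
        self.outgroup_singles(data)
        calls, _ = self._run(data, tree22, search=_HitEverything())
        (call,) = [c for c in calls if c.clade == "gnathostomes"]
        assert call.filter_flags["F6"] is Flag.FAIL and not call.is_dso
        calls, _ = self._run(data, tree22, search=_HitNothing())
        (call,) = [c for c in calls if c.clade == "gnathostomes"]
        assert call.filter_flags["F6"] is Flag.PASS and call.is_dso

    def test_every_lineage_specific_pair_gets_exactly_one_class(self, tree22):
        data = hits_for_carriers(tree22, GNATHOSTOMES + ["arctic_lamprey"])
        self.outgroup_singles(data)
        calls, _ = self._run(data, tree22)
        for c in calls:
            assert c.klass in (Klass.CLASS1, Klass.CLASS2)
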