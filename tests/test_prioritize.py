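"""Variant filtering cascades, region classification, codon arithmetic and
MNV-aware consequence annotation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from recmap.genes import make_toy_gene
from recmap.prioritize import (
    CdsVariant,
    CodonGroup,
    KnownCatalogue,
    VariantRecord,
    annotate_codon_group,
    annotate_cds_variants,
    cascade_a,
    cascade_b,
    classify_region,
    codon_index,
    filter_known_or_in_controls,
    genomic_to_cds_variant,
    group_codon_mnv,
    percent_removed,
    translate_codon,
)

# hard-coded standard genetic code, the independent reference for translation
STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def var(pos, ref="A", alt="C", chrom="1", **genos):
    return VariantRecord(chrom=chrom, pos=pos, ref=ref, alt=alt, genotypes=dict(genos))


def test_translate_all_64_codons_match_reference_table():
    for codon, aa in STANDARD_CODE.items():
        one, three = translate_codon(codon)
        assert one == aa
        if aa == "*":
            assert three == "Ter"


def test_translate_rejects_invalid_codons():
    for bad in ("AT", "ATGC", "ANU", "atx"):
        with pytest.raises(ValueError):
            translate_codon(bad)


@pytest.mark.parametrize(
    "pos, expected",
    [(2248, 750), (2250, 750), (2244, 748), (1, 1), (3, 1), (4, 2)],
)
def test_codon_index(pos, expected):
    assert codon_index(pos) == expected


def test_codon_index_out_of_range():
    with pytest.raises(ValueError):
        codon_index(0)
    with pytest.raises(ValueError):
        codon_index(2428, cds_length=2427)


def test_group_codon_mnv_splits_cluster_correctly(toy_gene):
    cvs = [
        CdsVariant(2244, "G", "C"),
        CdsVariant(2248, "T", "C"),
        CdsVariant(2250, "C", "A"),
    ]
    groups = group_codon_mnv(cvs, toy_gene)
    assert [(g.codon_index, len(g.members)) for g in groups] == [(748, 1), (750, 2)]


def test_group_codon_mnv_same_codon_and_duplicates(toy_gene):
    cvs = [CdsVariant(1, "A", "C"), CdsVariant(2, "T", "C"), CdsVariant(3, "G", "C")]
    groups = group_codon_mnv(cvs, toy_gene)
    assert len(groups) == 1 and groups[0].codon_index == 1
    with pytest.raises(ValueError, match="duplicate"):
        group_codon_mnv([CdsVariant(5, "A", "C"), CdsVariant(5, "A", "G")], toy_gene)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(st.sets(st.integers(1, 60), min_size=1, max_size=6))
def test_grouping_equals_same_codon_closure_oracle(positions):
    gene = make_toy_gene(np.random.default_rng(7))
    cvs = [CdsVariant(p, gene.cds_base(p), "A" if gene.cds_base(p) != "A" else "G")
           for p in sorted(positions)]
    groups = group_codon_mnv(cvs, gene)
    # oracle: brute-force pairwise same-codon closure
    expected = {}
    for p in sorted(positions):
        expected.setdefault((p - 1) // 3, []).append(p)
    assert sorted((g.codon_index, tuple(m.cds_pos for m in g.members)) for g in groups) == \
        sorted((ci + 1, tuple(ps)) for ci, ps in expected.items())


def test_joint_annotation_of_the_cluster(toy_gene):
    grp = CodonGroup(
        gene_id=toy_gene.gene_id, codon_index=750,
        members=(CdsVariant(2248, "T", "C"), CdsVariant(2250, "C", "A")),
    )
    rec = annotate_codon_group(grp, toy_gene.cds_sequence)
    assert (rec.ref_codon, rec.alt_codon) == ("TAC", "CAA")
    assert (rec.ref_aa, rec.alt_aa) == ("Y", "Q")
    assert rec.consequence == "missense"
    assert rec.short_label == "Y750Q"
    assert rec.p_label == "p.Tyr750Gln"
    assert rec.c_labels == ("c.2248T>C", "c.2250C>A")


def test_silent_member_annotates_synonymous(toy_gene):
    grp = CodonGroup(
        gene_id=toy_gene.gene_id, codon_index=748, members=(CdsVariant(2244, "G", "C"),)
    )
    rec = annotate_codon_group(grp, toy_gene.cds_sequence)
    assert (rec.ref_codon, rec.alt_codon) == ("TCG", "TCC")
    assert rec.consequence == "synonymous"
    assert rec.short_label == "S748"


def test_naive_per_variant_annotation_would_miscall_the_cluster(toy_gene):
    """c.2250C>A alone turns TAC into the stop TAA: per-variant annotation
    calls nonsense where the joint MNV is missense."""
    grp = CodonGroup(
        gene_id=toy_gene.gene_id, codon_index=750, members=(CdsVariant(2250, "C", "A"),)
    )
    rec = annotate_codon_group(grp, toy_gene.cds_sequence)
    assert rec.consequence == "nonsense"
    assert rec.alt_codon == "TAA"


def test_ref_mismatch_is_reported_with_position(toy_gene):
    grp = CodonGroup(
        gene_id=toy_gene.gene_id, codon_index=750, members=(CdsVariant(2248, "A", "C"),)
    )
    with pytest.raises(ValueError, match="2248"):
        annotate_codon_group(grp, toy_gene.cds_sequence)


def test_strand_invariance_of_annotation(toy_gene):
    """Annotating the mirrored (reverse-complement genome, minus-strand)
    rendition of the gene yields the identical consequence record."""
    L = 30_000_000
    mirror = toy_gene.mirrored(L)
    fwd_vars = [
        var(toy_gene.cds_to_genomic(2248), "T", "C", s=2),
        var(toy_gene.cds_to_genomic(2250), "C", "A", s=2),
    ]
    rev_vars = [
        var(L - toy_gene.cds_to_genomic(2248) + 1, "A", "G", s=2),
        var(L - toy_gene.cds_to_genomic(2250) + 1, "G", "T", s=2),
    ]
    ann_f = annotate_cds_variants(fwd_vars, toy_gene)
    ann_r = annotate_cds_variants(rev_vars, mirror)
    assert len(ann_f) == len(ann_r) == 1
    rf, rr = ann_f[0][1], ann_r[0][1]
    assert rf == rr


def test_region_classification_against_per_base_oracle(toy_gene):
    """Walk a ladder of positions across the whole gene plus flanks and
    compare with a brute-force per-base classifier."""
    span = toy_gene.span
    cds_genomic = {toy_gene.cds_to_genomic(c) for c in range(1, toy_gene.cds_length + 1)}
    exonic = set()
    for s, e in toy_gene.exons:
        exonic.update(range(s, e + 1))

    def oracle(p):
        if p in cds_genomic:
            return "CDS"
        if p in exonic:
            return "exonic-noncoding"
        if span[0] <= p <= span[1]:
            return "intronic"
        return "intergenic"

    for p in range(span[0] - 25, span[1] + 26, 7):
        assert classify_region(p, toy_gene) == oracle(p)
    # boundary conventions, explicitly
    assert classify_region(toy_gene.exons[0][0], toy_gene) == "exonic-noncoding"  # 5' UTR
    assert classify_region(span[0] - 1, toy_gene) == "intergenic"
    assert classify_region(toy_gene.exons[0][1] + 1, toy_gene) == "intronic"


def test_filter_removes_control_carriers_and_catalogued():
    catalogue = KnownCatalogue(frozenset({("1", 30, "A", "C")}))
    v1 = var(10, ctrl=1, case=2)  # het in a control -> removed
    v2 = var(20, ctrl=0, case=2)  # clean -> kept
    v3 = var(30, ctrl=0, case=2)  # catalogued -> removed
    kept, removed = filter_known_or_in_controls([v1, v2, v3], ["ctrl"], catalogue)
    assert kept == [v2] and removed == 2


def test_filter_identity_with_empty_catalogue_and_clean_controls():
    vs = [var(i, ctrl=0, case=2) for i in (1, 2, 3)]
    kept, removed = filter_known_or_in_controls(vs, ["ctrl"], KnownCatalogue(frozenset()))
    assert kept == vs and removed == 0


def test_filter_unknown_control_id():
    with pytest.raises(KeyError, match="ghost"):
        filter_known_or_in_controls([var(1, a=0)], ["ghost"], KnownCatalogue(frozenset()))


def test_percent_removed_rounding():
    assert percent_removed(1733, 2162) == 80
    assert percent_removed(0, 0) == 0
    assert percent_removed(5, 5) == 100


def test_cascade_a_empty_and_all_catalogued(toy_gene):
    empty = cascade_a([], ["c1"], ["k1"], KnownCatalogue(frozenset()), toy_gene)
    assert empty.total == 0 and empty.aa_changing == 0
    vs = [var(i, c1=2, k1=0) for i in (5, 6)]
    cat = KnownCatalogue(frozenset(v.key for v in vs))
    rep = cascade_a(vs, ["c1"], ["k1"], cat, toy_gene)
    assert rep.percent_removed_step1 == 100 and rep.remaining == 0


def test_cascade_a_on_synthetic_callset_matches_truth(
    default_population, toy_gene, causal_cluster, wgs_cohorts, wgs_callset
):
    cases, carriers, noncarriers = wgs_cohorts
    variants, catalogue, truth = wgs_callset
    rep = cascade_a(variants, cases, noncarriers, catalogue, toy_gene)
    assert rep.total == len(truth)
    # telescoping
    counts = [rep.total, rep.remaining, rep.hom_in_all_cases, rep.in_transcribed,
              rep.in_orf, rep.aa_changing]
    assert all(a >= b for a, b in zip(counts, counts[1:]))
    assert rep.removed_known_or_in_controls + rep.remaining == rep.total
    # step-1 truth: removed iff catalogued or alt seen in a control
    expected_removed = 0
    for v in variants:
        in_ctrl = any(v.genotypes[s] in (1, 2) for s in noncarriers)
        expected_removed += int(in_ctrl or v in catalogue)
    assert rep.removed_known_or_in_controls == expected_removed
    # the causal cluster ends up in the amino-acid-changing set
    aa_keys = {v.key for v in rep.retained["aa_changing"]}
    missense_keys = {
        (causal_cluster.chrom, p, r, a)
        for p, r, a in zip(causal_cluster.genomic_positions,
                           causal_cluster.ref_alleles, causal_cluster.alt_alleles)
        if p in (toy_gene.cds_to_genomic(2248), toy_gene.cds_to_genomic(2250))
    }
    assert missense_keys <= aa_keys


def test_cascade_b_exclusion_rules(toy_gene):
    case, carr, nonc = ["A"], ["B"], ["C"]
    ok = var(100, A=2, B=1, C=0)
    het_in_nonc = var(101, A=2, B=1, C=1)
    hom_in_carr = var(102, A=2, B=2, C=0)
    missing_case = var(103, A=-1, B=1, C=0)
    rep = cascade_b([ok, het_in_nonc, hom_in_carr, missing_case], case, carr, nonc, toy_gene)
    assert [v.pos for v in rep.survivors] == [100]


def test_cascade_b_missing_handling_is_configurable(toy_gene):
    v = var(100, A=-1, B=1, C=0)
    rep = cascade_b([v], ["A"], ["B"], ["C"], toy_gene, missing_disqualifies=False)
    assert rep.survivors == [v]


def test_cascade_b_overlapping_cohorts_fail(toy_gene):
    with pytest.raises(ValueError, match="disjoint"):
        cascade_b([], ["A"], ["A"], ["C"], toy_gene)


def test_cascade_b_on_synthetic_callset(
    default_population, toy_gene, causal_cluster, wgs_cohorts, wgs_callset
):
    cfg = default_population[0]
    cases, carriers, noncarriers = wgs_cohorts
    variants, catalogue, truth = wgs_callset
    rep = cascade_b(variants, cases, carriers, noncarriers, toy_gene)
    survivor_keys = {v.key for v in rep.survivors}
    cluster_keys = {
        (causal_cluster.chrom, p, r, a)
        for p, r, a in zip(causal_cluster.genomic_positions,
                           causal_cluster.ref_alleles, causal_cluster.alt_alleles)
    }
    assert cluster_keys <= survivor_keys
    # every planted linked variant survives; breakdown partitions survivors
    linked = truth[truth["kind"].str.startswith(("linked", "cluster"))]
    assert len(rep.survivors) >= len(linked)
    assert sum(rep.breakdown.values()) == len(rep.survivors)
    assert rep.breakdown["intergenic"] >= cfg.n_linked_intergenic
    assert rep.breakdown["intronic"] >= cfg.n_linked_intronic
    assert sum(rep.coding_split.values()) == rep.breakdown["coding"]
    # the only non-synonymous consequence is the planted codon-750 group
    nonsyn = [c for c in rep.consequences if c.consequence != "synonymous"]
    assert [c.short_label for c in nonsyn] == ["Y750Q"]


def test_reports_are_order_invariant(
    default_population, toy_gene, wgs_cohorts, wgs_callset
):
    cases, carriers, noncarriers = wgs_cohorts
    variants, catalogue, _ = wgs_callset
    rep1 = cascade_a(variants, cases, noncarriers, catalogue, toy_gene)
    rep2 = cascade_a(variants[::-1], cases, noncarriers, catalogue, toy_gene)
    assert rep1.counts() == rep2.counts()
    assert {v.key for v in rep1.retained["aa_changing"]} == \
        {v.key for v in rep2.retained["aa_changing"]}


def test_catalogue_tsv_round_trip(tmp_path, wgs_callset):
    _, catalogue, _ = wgs_callset
    p = tmp_path / "cat.tsv"
    catalogue.write_tsv(p)
    assert KnownCatalogue.read_tsv(p) == catalogue
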