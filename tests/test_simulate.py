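"""Simulator contracts: pedigree structure, gene-drop statistics, genotype
emission, callset construction, and the trace model."""

import numpy as np
import pytest
from scipy import stats

from recmap.genes import make_causal_cluster, make_toy_gene
from recmap.io import read_ped_map, read_vcf_matrix, write_ped_map, write_vcf_matrix
from recmap.kinetics import fit_activation
from recmap.simulate import (
    QuotaError,
    SimConfig,
    TraceSimSpec,
    build_population,
    default_trace_spec,
    emit_array_genotypes,
    emit_wgs_callset,
    simulate_traces,
)

SMALL = SimConfig(
    chromosome_lengths=(5_000_000,),
    marker_spacing=100_000,
    n_founders=20,
    n_generations=3,
    target_n_cases=0,
)


def test_zero_generations_gives_founders_only():
    cfg = SimConfig(n_generations=0, target_n_cases=0, chromosome_lengths=(2_000_000,))
    ped, haps = build_population(cfg, seed=5)
    assert len(ped) == cfg.n_founders
    assert all(i.is_founder for i in ped)
    assert ped.affected_ids() == []


def test_unreachable_case_quota_raises_named_error():
    cfg = SimConfig(n_generations=0, target_n_cases=3, max_attempts=3,
                    chromosome_lengths=(2_000_000,))
    with pytest.raises(QuotaError, match="target_n_cases=3"):
        build_population(cfg, seed=5)


def test_affected_iff_causal_homozygous_and_trace_to_founder(default_population):
    _, ped, haps = default_population
    for ind in ped:
        d = haps.causal_dosage(ind.id)
        assert (ind.phenotype == "affected") == (d == 2)
        assert (ind.carrier_state == "homozygous") == (d == 2)
        assert (ind.carrier_state == "carrier") == (d == 1)
    # both parental paths of every affected reach the single founder carrier
    carrier_founder = [f.id for f in ped.founders()
                      if haps.causal_dosage(f.id) > 0]
    assert carrier_founder == ["G0_000"]

    def reaches_any_path(iid, target):
        ind = ped[iid]
        if iid == target:
            return True
        return any(
            reaches_any_path(p, target)
            for p in (ind.sire, ind.dam)
            if p is not None
        )

    for case in ped.affected_ids():
        ind = ped[case]
        assert reaches_any_path(ind.sire, "G0_000")
        assert reaches_any_path(ind.dam, "G0_000")


def test_mendelian_consistency_no_allele_from_nowhere(default_population):
    _, ped, haps = default_population
    for chrom in haps.gmap.chroms:
        alleles = haps.alleles[chrom]
        for ind in ped:
            if ind.is_founder:
                continue
            i = haps.index_of(ind.id)
            s = haps.index_of(ind.sire)
            d = haps.index_of(ind.dam)
            # haplotype 0 came from the sire, 1 from the dam
            assert (np.isin(alleles[i, 0], alleles[s]).all())
            ok_s = (alleles[i, 0] == alleles[s, 0]) | (alleles[i, 0] == alleles[s, 1])
            ok_d = (alleles[i, 1] == alleles[d, 0]) | (alleles[i, 1] == alleles[d, 1])
            assert ok_s.all() and ok_d.all()


def test_origin_labels_are_single_parent_mosaics(default_population):
    _, ped, haps = default_population
    for chrom in haps.gmap.chroms:
        org = haps.origins[chrom]
        for ind in list(ped)[:50]:
            if ind.is_founder:
                continue
            i = haps.index_of(ind.id)
            s = haps.index_of(ind.sire)
            labels = set(org[i, 0].tolist())
            assert labels <= set(org[s].ravel().tolist())


def test_truth_ibd_segment_covers_causal_position(default_population):
    _, ped, haps = default_population
    chrom, lo, hi = haps.truth_ibd_interval(ped.affected_ids())
    assert chrom == haps.causal_chrom
    assert lo <= haps.causal_pos + 30_000 and hi >= haps.causal_pos - 30_000


def test_crossover_count_is_poisson_with_map_length():
    """10,000 meioses on a 100-cM chromosome: mean crossover count within
    3 standard errors of 1.0 (Haldane, no interference)."""
    from recmap.simulate import _gamete_phase

    rng = np.random.default_rng(42)
    length_cm = 100.0
    q = np.linspace(0, length_cm, 50)
    switches = []
    for _ in range(10_000):
        phase = _gamete_phase(rng, length_cm, q)
        switches.append(int((np.diff(phase) != 0).sum()))
    mean = np.mean(switches)
    se = np.std(switches) / np.sqrt(len(switches))
    # dense 50-marker grid slightly undercounts crossovers (double hits in a
    # 2-cM bin cancel); allow for that with a one-sided lower margin
    assert 1.0 - 3 * se - 0.03 <= mean <= 1.0 + 3 * se


def test_gene_drop_zero_map_transmits_whole_haplotypes():
    """With a 0-cM map every gamete is an unrecombined copy of one parental
    haplotype."""
    from recmap.simulate import (
        GeneticMap, Individual, Pedigree, founder_haplotypes, gene_drop,
        _make_genetic_map,
    )

    cfg = SimConfig(chromosome_lengths=(1_000_000,), marker_spacing=50_000,
                    n_founders=4, cm_per_mb=0.0)
    gmap = _make_genetic_map(cfg)
    ped = Pedigree()
    for k, sex in enumerate("MFMF"):
        ped.add(Individual(id=f"G0_{k:03d}", sire=None, dam=None, sex=sex, generation=0))
    ped.add(Individual(id="kid", sire="G0_000", dam="G0_001", sex="M", generation=1))
    rng = np.random.default_rng(0)
    fh = founder_haplotypes(cfg, gmap, ped, rng)
    haps = gene_drop(ped, gmap, fh, 1)
    kid = haps.alleles["1"][haps.index_of("kid")]
    sire = haps.alleles["1"][haps.index_of("G0_000")]
    dam = haps.alleles["1"][haps.index_of("G0_001")]
    assert any((kid[0] == sire[h]).all() for h in (0, 1))
    assert any((kid[1] == dam[h]).all() for h in (0, 1))


def test_gene_drop_marker_outside_map_fails():
    from recmap.simulate import (
        GeneticMap, Individual, Pedigree, founder_haplotypes, gene_drop,
        _make_genetic_map,
    )

    cfg = SimConfig(chromosome_lengths=(1_000_000,), marker_spacing=50_000, n_founders=2)
    gmap = _make_genetic_map(cfg)
    ped = Pedigree()
    ped.add(Individual(id="G0_000", sire=None, dam=None, sex="M", generation=0))
    ped.add(Individual(id="G0_001", sire=None, dam=None, sex="F", generation=0))
    fh = founder_haplotypes(cfg, gmap, ped, np.random.default_rng(0))
    bad_map = GeneticMap(
        chroms=("1",), lengths_bp={"1": 400_000},
        positions_bp={"1": gmap.positions_bp["1"]}, cm_per_mb=1.0,
    )
    with pytest.raises(ValueError, match="outside"):
        gene_drop(ped, bad_map, fh, 1)


def test_carrier_transmission_is_mendelian(default_population):
    """Carrier x noncarrier offspring are carriers ~half the time."""
    _, ped, haps = default_population
    n = k = 0
    for ind in ped:
        if ind.is_founder:
            continue
        ds = haps.causal_dosage(ind.sire)
        dd = haps.causal_dosage(ind.dam)
        if {ds, dd} == {1, 0}:
            n += 1
            k += haps.causal_dosage(ind.id)
    assert n >= 50
    lo, hi = stats.binom.interval(0.999, n, 0.5)
    assert lo <= k <= hi


def test_seed_determinism_byte_identical(tmp_path):
    cfg = SMALL
    out = []
    for _ in range(2):
        ped, haps = build_population(cfg, seed=9)
        gm = emit_array_genotypes(haps, 0.01, seed=3)
        p = tmp_path / f"run{len(out)}.vcf"
        write_vcf_matrix(gm, p)
        out.append(p.read_bytes())
    assert out[0] == out[1]


def test_array_genotypes_equal_haplotype_sums_without_error(default_population):
    _, ped, haps = default_population
    gm = emit_array_genotypes(haps, 0.0, seed=2)
    start = 0
    for chrom in haps.gmap.chroms:
        n = len(haps.gmap.positions_bp[chrom])
        expected = haps.alleles[chrom].sum(axis=1)
        np.testing.assert_array_equal(gm.genotypes[:, start : start + n], expected)
        start += n


def test_genotyping_error_rate_calibrated(default_population):
    _, ped, haps = default_population
    truth = emit_array_genotypes(haps, 0.0, seed=2)
    noisy = emit_array_genotypes(haps, 0.01, seed=2)
    n = truth.genotypes.size
    assert n >= 100_000
    disc = (truth.genotypes != noisy.genotypes).mean()
    assert 0.008 <= disc <= 0.012


def test_vcf_and_ped_map_round_trip(default_population, tmp_path):
    _, ped, haps = default_population
    gm = emit_array_genotypes(haps, 0.005, seed=4)
    vcf = tmp_path / "g.vcf"
    write_vcf_matrix(gm, vcf, contigs={c: haps.gmap.lengths_bp[c] for c in haps.gmap.chroms})
    back = read_vcf_matrix(vcf)
    assert back.sample_ids == gm.sample_ids
    np.testing.assert_array_equal(back.genotypes, gm.genotypes)
    assert back.markers[["chrom", "pos", "ref", "alt"]].equals(
        gm.markers[["chrom", "pos", "ref", "alt"]].astype({"chrom": str})
    )
    ped_p, map_p = tmp_path / "g.ped", tmp_path / "g.map"
    write_ped_map(gm, ped_p, map_p)
    back2 = read_ped_map(ped_p, map_p, ref_alt=gm.markers)
    assert back2.sample_ids == gm.sample_ids
    np.testing.assert_array_equal(back2.genotypes, gm.genotypes)


def test_wgs_cluster_genotypes_follow_carrier_state(
    default_population, wgs_callset, causal_cluster
):
    _, ped, haps = default_population
    variants, catalogue, truth = wgs_callset
    cluster_pos = set(causal_cluster.genomic_positions)
    cluster_vars = [v for v in variants if v.pos in cluster_pos]
    assert len(cluster_vars) == 3
    for v in cluster_vars:
        assert v not in catalogue
        for s, g in v.genotypes.items():
            assert g == haps.causal_dosage(s)


def test_wgs_background_count_within_poisson_bounds(default_population, toy_gene,
                                                    causal_cluster):
    cfg, ped, haps = default_population
    samples = ped.affected_ids()[:4]
    variants, _, truth = emit_wgs_callset(
        haps, toy_gene, causal_cluster, cfg, seed=21, sample_ids=samples
    )
    n_bg = int(truth["kind"].str.startswith("background").sum())
    region_len = 2 * cfg.wgs_halfwidth + (
        max(causal_cluster.genomic_positions) - min(causal_cluster.genomic_positions)
    ) + 1
    lam = cfg.background_variant_density * region_len / 1000.0
    lo, hi = stats.poisson.interval(0.99, lam)
    assert lo <= n_bg <= hi


def test_wgs_catalogue_never_contains_cluster_or_private(wgs_callset):
    variants, catalogue, truth = wgs_callset
    for _, row in truth.iterrows():
        key = (row["chrom"], row["pos"], row["ref"], row["alt"])
        if row["kind"] != "background_common":
            assert key not in catalogue
        assert row["in_catalogue"] == (key in catalogue)


def test_cluster_outside_exon_is_rejected(default_population, toy_gene, causal_cluster):
    from dataclasses import replace

    cfg, ped, haps = default_population
    intron_pos = toy_gene.exons[0][1] + 5
    bad = replace(causal_cluster,
                  genomic_positions=(intron_pos, intron_pos + 2, intron_pos + 4))
    with pytest.raises(ValueError, match="outside every exon"):
        emit_wgs_callset(haps, toy_gene, bad, cfg, seed=1,
                         sample_ids=ped.affected_ids()[:2])


# ---- trace model ----------------------------------------------------------


def test_trace_reaches_steady_amplitude():
    spec = default_trace_spec(noise_sd=0.0, tau_act=100.0)
    tr = simulate_traces(spec, 1, seed=0)[0]
    for v in (80.0, 40.0):
        a = spec.amplitude(v)
        tail = tr.currents[v][tr.time_ms >= 10 * spec.tau_act]
        assert np.all(np.abs(tail - a) <= 1e-3 * abs(a) + 1e-12)


def test_noiseless_trace_refit_recovers_tau():
    spec = default_trace_spec(noise_sd=0.0, tau_act=341.0, sampling_interval=1.0)
    tr = simulate_traces(spec, 1, seed=0)[0]
    fit = fit_activation(tr, voltage=80.0, window_ms=250.0)
    assert fit.converged
    assert abs(fit.tau_ms - 341.0) / 341.0 < 1e-6


def test_instantaneous_only_current_has_no_time_dependence():
    spec = default_trace_spec(noise_sd=0.0, instantaneous_fraction=1.0)
    tr = simulate_traces(spec, 1, seed=0)[0]
    i = tr.currents[80.0]
    assert np.allclose(i, i[0])
    fit = fit_activation(tr)
    assert (not fit.converged) or abs(fit.amplitude) < 1e-9


def test_nonpositive_tau_rejected():
    with pytest.raises(ValueError):
        simulate_traces(default_trace_spec(tau_act=0.0), 1, seed=0)
    with pytest.raises(ValueError):
        simulate_traces(default_trace_spec(tau_deact=-5.0), 1, seed=0)
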