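import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gbody import parclip
from gbody.parclip import BindingSite, QCParams
from gbody.simulate import make_annotation, simulate_site_rpm_mixture


# ---------------------------------------------------------------------------
# Raw-read QC
# ---------------------------------------------------------------------------

ADAPTER = QCParams().three_prime_adapter


def fastq(seq, qual=None, title="r"):
    return (title, seq, qual if qual is not None else "I" * len(seq))


def with_adapter(insert, qual_char="I"):
    seq = insert + ADAPTER
    return (insert, seq, qual_char * len(seq))


def test_short_read_removed_under_min_length():
    insert, seq, qual = with_adapter("ACGT" * 4 + "A")  # 17 nt insert
    _, report = parclip.filter_raw_reads([("r", seq, qual)])
    assert report["min_length"] == 1 and report["passed"] == 0


def test_homopolymer_a_removed_despite_perfect_quality():
    insert, seq, qual = with_adapter("A" * 20)
    survivors, report = parclip.filter_raw_reads([("r", seq, qual)])
    assert report["homopolymer_A"] == 1 and not survivors


def test_fixture_of_ten_reads_three_violations():
    """Hand-evaluated fixture: exactly 3 reads each violating one rule."""
    good = [with_adapter("ACGTACGTACGTACGTACGT")[1:] for _ in range(7)]
    bad = [
        with_adapter("ACGTACGTACGTACGT")[1:],  # 16 nt: min_length
        ("A" * 20 + ADAPTER, "I" * (20 + len(ADAPTER))),  # homopolymer
        ("ACGTACGTACGTACGTACGTACGT", "I" * 24),  # missing 3' adapter
    ]
    reads = [("r%d" % i, s, q) for i, (s, q) in enumerate(good + bad)]
    survivors, report = parclip.filter_raw_reads(reads)
    assert len(survivors) == 7
    assert report["min_length"] == 1
    assert report["homopolymer_A"] == 1
    assert report["missing_3p_adapter"] == 1


def test_quality_rules_use_spec_boundaries():
    insert = "ACGTACGTACGTACGTACGT"
    # 5 bases below q10 (phred 9 = '*') -> removed; 4 -> kept
    for n_low, removed in [(5, True), (4, False)]:
        qual = "*" * n_low + "I" * (len(insert) + len(ADAPTER) - n_low)
        _, report = parclip.filter_raw_reads([("r", insert + ADAPTER, qual)])
        assert (report["low_quality_q10"] == 1) is removed
    # 7 bases below q13 (phred 12 = '-') -> removed; 6 -> kept
    for n_low, removed in [(7, True), (6, False)]:
        qual = "-" * n_low + "I" * (len(insert) + len(ADAPTER) - n_low)
        _, report = parclip.filter_raw_reads([("r", insert + ADAPTER, qual)])
        assert (report["low_quality_q13"] == 1) is removed


def test_adapter_ligation_product_removed():
    five = QCParams().five_prime_adapter
    seq = five + "ACGTACGTACGTACGT" + ADAPTER
    _, report = parclip.filter_raw_reads([("r", seq, "I" * len(seq))])
    assert report["adapter_ligation"] == 1


def test_malformed_fastq_names_record_index():
    reads = [("r0", "ACGT", "II")]  # qual length mismatch
    with pytest.raises(ValueError, match="record 0"):
        parclip.filter_raw_reads(reads)


# ---------------------------------------------------------------------------
# Site assembly vs per-position coverage oracle
# ---------------------------------------------------------------------------

def reads_frame(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "strand", "conversion_count"])


def oracle_sites(reads, total_mapped, max_conversions=2):
    """Brute force: per-position coverage arrays and connected components."""
    kept = reads[reads["conversion_count"] <= max_conversions]
    out = []
    for (chrom, strand), grp in kept.groupby(["chrom", "strand"], sort=True):
        hi = int(grp["end"].max())
        cov = np.zeros(hi + 1, dtype=int)
        for s, e in zip(grp["start"], grp["end"]):
            cov[s:e] += 1
        covered = cov > 0
        pos = 0
        while pos <= hi:
            if not covered[pos]:
                pos += 1
                continue
            start = pos
            while pos <= hi and covered[pos]:
                pos += 1
            end = pos
            in_site = (grp["start"] < end) & (grp["end"] > start)
            n_conv = int((grp.loc[in_site, "conversion_count"] >= 1).sum())
            if n_conv >= 1:
                rpm = cov[start:end].mean() / (total_mapped / 1e6)
                out.append((str(chrom), str(strand), start, end, rpm, n_conv))
    return sorted(out)


def sites_tuples(sites):
    return sorted(
        (s.chrom, s.strand, s.start, s.end, s.rpm, s.n_conversion_reads) for s in sites
    )


def test_two_disjoint_single_read_islands():
    reads = reads_frame(
        [("chrI", 100, 130, "+", 1), ("chrI", 500, 530, "+", 1)]
    )
    sites = parclip.assemble_binding_sites(reads, total_mapped=1_000_000)
    assert len(sites) == 2
    assert all(np.isclose(s.rpm, 1.0) for s in sites)


def test_no_conversions_no_high_confidence_sites():
    reads = reads_frame([("chrI", 100, 130, "+", 0)] * 10)
    assert parclip.assemble_binding_sites(reads, total_mapped=10_000) == []


def test_reads_with_three_conversions_excluded_before_aggregation():
    reads = reads_frame(
        [("chrI", 100, 130, "+", 3), ("chrI", 125, 155, "+", 1)]
    )
    sites = parclip.assemble_binding_sites(reads, total_mapped=1_000_000)
    assert len(sites) == 1
    assert (sites[0].start, sites[0].end) == (125, 155)


@pytest.mark.parametrize("seed", range(6))
def test_assembly_matches_coverage_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 200
    starts = rng.integers(0, 3_000, size=n)
    lengths = rng.integers(20, 45, size=n)
    rows = [
        (
            rng.choice(["chrI", "chrII"]),
            int(s),
            int(s + l),
            rng.choice(["+", "-"]),
            int(rng.integers(0, 4)),
        )
        for s, l in zip(starts, lengths)
    ]
    reads = reads_frame(rows)
    got = sites_tuples(parclip.assemble_binding_sites(reads, total_mapped=10_000))
    expected = oracle_sites(reads, total_mapped=10_000)
    assert len(got) == len(expected)
    for g, e in zip(got, expected):
        assert g[:4] == e[:4] and g[5] == e[5]
        assert np.isclose(g[4], e[4])


def test_assembly_invariant_to_read_order(rng):
    rows = [
        ("chrI", int(s), int(s) + 30, "+", int(c))
        for s, c in zip(rng.integers(0, 1_000, 50), rng.integers(0, 3, 50))
    ]
    reads = reads_frame(rows)
    shuffled = reads.sample(frac=1.0, random_state=0).reset_index(drop=True)
    a = sites_tuples(parclip.assemble_binding_sites(reads, total_mapped=10_000))
    b = sites_tuples(parclip.assemble_binding_sites(shuffled, total_mapped=10_000))
    assert a == b


def test_assembly_rejects_bad_inputs():
    reads = reads_frame([("chrI", -5, 25, "+", 1)])
    with pytest.raises(ValueError, match="negative"):
        parclip.assemble_binding_sites(reads, total_mapped=100)
    with pytest.raises(ValueError, match="total_mapped"):
        parclip.assemble_binding_sites(
            reads_frame([("chrI", 0, 30, "+", 1)] * 5), total_mapped=3
        )
    assert parclip.assemble_binding_sites(reads_frame([]), total_mapped=10) == []


# ---------------------------------------------------------------------------
# K-S statistic
# ---------------------------------------------------------------------------

def ks_oracle(x, y):
    """Brute-force double loop over all pooled evaluation points."""
    best = 0.0
    for v in list(x) + list(y):
        fx = sum(1 for a in x if a <= v) / len(x)
        fy = sum(1 for b in y if b <= v) / len(y)
        best = max(best, abs(fx - fy))
    return best


def test_ks_identical_samples_zero():
    assert parclip.ks_two_sample([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0


def test_ks_disjoint_supports_one():
    assert parclip.ks_two_sample([0.0], [1.0]) == 1.0


def test_ks_empty_sample_rejected():
    with pytest.raises(ValueError):
        parclip.ks_two_sample([], [1.0])


def test_ks_matches_brute_force_and_scipy(rng):
    for _ in range(20):
        x = rng.normal(size=50)
        y = rng.normal(0.3, 1.2, size=40)
        d = parclip.ks_two_sample(x, y)
        assert np.isclose(d, ks_oracle(x, y), atol=1e-12)
        assert np.isclose(d, stats.ks_2samp(x, y).statistic, atol=1e-12)


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    x=st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=30),
    y=st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=30),
)
def test_ks_property_matches_oracle_with_ties(x, y):
    d = parclip.ks_two_sample(x, y)
    assert 0.0 <= d <= 1.0
    assert np.isclose(d, ks_oracle(x, y), atol=1e-12)


def test_row_ks_agrees_with_scalar(rng):
    x = rng.exponential(size=(5, 12))
    y = rng.exponential(size=(5, 17))
    rows = parclip._ks_rows(x, y)
    for i in range(5):
        assert np.isclose(rows[i], parclip.ks_two_sample(x[i], y[i]), atol=1e-12)


# ---------------------------------------------------------------------------
# Empirical RPM threshold
# ---------------------------------------------------------------------------

def test_full_fraction_subsamples_give_zero_ks(rng):
    vals = rng.exponential(size=40)
    d = parclip._mean_subsample_ks(vals, frac=1.0, n_iter=10, rng=rng)
    assert d == 0.0


def test_degenerate_equal_rpms_choose_grid_minimum():
    rpm = np.full(30, 5.0)
    curve = parclip.empirical_rpm_threshold(rpm, n_iter=50, seed=0)
    assert curve.chosen == curve.grid[0]
    finite = curve.mean_stat[np.isfinite(curve.mean_stat)]
    assert np.allclose(finite, 0.0)


def test_threshold_deterministic_given_seed():
    import warnings

    rpm, _ = simulate_site_rpm_mixture(seed=5)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # low n_iter may legitimately not stabilize
        a = parclip.empirical_rpm_threshold(rpm, n_iter=200, seed=42)
        b = parclip.empirical_rpm_threshold(rpm, n_iter=200, seed=42)
    assert a.chosen == b.chosen
    assert np.array_equal(a.mean_stat, b.mean_stat, equal_nan=True)


def test_threshold_requires_enough_sites():
    with pytest.raises(ValueError, match="smallest grid value"):
        parclip.empirical_rpm_threshold(np.ones(10), n_iter=10, seed=0)


def test_rpm_filter_monotone(rng):
    sites = [
        BindingSite("chrI", "+", i * 100, i * 100 + 40, rpm=float(r), n_conversion_reads=1)
        for i, r in enumerate(rng.exponential(5.0, size=50))
    ]
    prev = parclip.filter_sites_by_rpm(sites, 0.0)
    for t in np.linspace(0, 10, 15):
        cur = parclip.filter_sites_by_rpm(sites, t)
        assert set(id(s) for s in cur) <= set(id(s) for s in prev)
        assert all(s.rpm >= t for s in cur)
        prev = cur


def test_threshold_separates_planted_mixture_at_defaults():
    """On the planted noise/signal RPM mixture the chosen threshold excludes
    >= 95% of noise sites while keeping >= 95% of signal sites."""
    for seed in (0, 1, 2):
        rpm, lab = simulate_site_rpm_mixture(seed=seed)
        curve = parclip.empirical_rpm_threshold(rpm, seed=seed + 100)
        noise, signal = rpm[~lab], rpm[lab]
        assert (noise < curve.chosen).mean() >= 0.95
        assert (signal >= curve.chosen).mean() >= 0.95


# ---------------------------------------------------------------------------
# Overlap classes
# ---------------------------------------------------------------------------

def site(chrom, strand, start, end, rpm=1.0, ds=""):
    return BindingSite(chrom, strand, start, end, rpm, 1, ds)


def test_identical_sites_both_labeled_identical():
    sets = {
        "a": [site("chrI", "+", 100, 150)],
        "b": [site("chrI", "+", 100, 150)],
    }
    labels = parclip.classify_site_overlap(sets, identical_tol=0)
    assert labels == {"a": ["identical"], "b": ["identical"]}


def test_partially_overlapping_sites():
    sets = {
        "a": [site("chrI", "+", 100, 150)],
        "b": [site("chrI", "+", 140, 190)],
    }
    labels = parclip.classify_site_overlap(sets)
    assert labels == {"a": ["overlapping"], "b": ["overlapping"]}


def test_opposite_strand_sites_are_unique():
    sets = {
        "a": [site("chrI", "+", 100, 150)],
        "b": [site("chrI", "-", 100, 150)],
    }
    labels = parclip.classify_site_overlap(sets)
    assert labels == {"a": ["unique"], "b": ["unique"]}


def overlap_oracle(site_sets, tol):
    labels = {}
    for ds, sites in site_sets.items():
        out = []
        for s in sites:
            others = [
                o
                for ds2, lst in site_sets.items()
                if ds2 != ds
                for o in lst
                if o.chrom == s.chrom and o.strand == s.strand
            ]
            if any(
                abs(o.start - s.start) <= tol and abs(o.end - s.end) <= tol
                for o in others
            ):
                out.append("identical")
            elif any(min(o.end, s.end) - max(o.start, s.start) >= 1 for o in others):
                out.append("overlapping")
            else:
                out.append("unique")
        labels[ds] = out
    return labels


def test_three_dataset_fixture_matches_all_pairs_oracle(rng):
    sets = {}
    for ds in ("a", "b", "c"):
        sets[ds] = [
            site(
                rng.choice(["chrI", "chrII"]),
                rng.choice(["+", "-"]),
                int(s),
                int(s) + int(rng.integers(20, 60)),
                ds=ds,
            )
            for s in rng.integers(0, 800, size=25)
        ]
    for tol in (0, 5):
        assert parclip.classify_site_overlap(sets, identical_tol=tol) == overlap_oracle(
            sets, tol
        )


def test_single_dataset_warns_all_unique():
    with pytest.warns(UserWarning, match="single dataset"):
        labels = parclip.classify_site_overlap({"a": [site("chrI", "+", 0, 10)]})
    assert labels == {"a": ["unique"]}


# ---------------------------------------------------------------------------
# Genic annotation
# ---------------------------------------------------------------------------

def test_midpoint_in_three_utr(annot):
    g = next(g for g in annot.genes if not g.is_ncRNA)
    mid = (g.three_utr[0] + g.three_utr[1]) // 2
    s = site(g.chrom, g.strand, mid - 5, mid + 5)
    labels, _ = parclip.annotate_sites([s], annot)
    assert labels == ["3'UTR"]


def test_all_ncrna_sites_normalize_to_one(annot):
    nc = [g for g in annot.genes if g.is_ncRNA]
    sites = [
        site(g.chrom, g.strand, g.cds[0] + 1, g.cds[0] + 21, rpm=2.0) for g in nc
    ]
    labels, fractions = parclip.annotate_sites(sites, annot)
    assert set(labels) == {"ncRNA"}
    assert np.isclose(fractions["ncRNA"], 1.0)
    assert np.isclose(sum(fractions.values()), 1.0)


def test_mixed_fixture_matches_hand_tally(annot, rng):
    sites, expected = [], {r: 0.0 for r in parclip.GENIC_REGIONS}
    for _ in range(30):
        g = annot.genes[rng.integers(0, len(annot.genes))]
        pos = int(rng.integers(g.start + 1, g.end - 1))
        s = site(g.chrom, g.strand, pos - 2, pos + 3, rpm=float(rng.exponential(2.0)))
        region = "ncRNA" if g.is_ncRNA else g.region_of(s.midpoint)
        expected[region] += s.rpm
        sites.append(s)
    total = sum(expected.values())
    labels, fractions = parclip.annotate_sites(sites, annot)
    for r in parclip.GENIC_REGIONS:
        assert np.isclose(fractions[r], expected[r] / total)
    assert np.isclose(sum(fractions.values()), 1.0, atol=1e-9)


def test_site_beyond_chromosome_rejected(annot):
    s = site("chrI", "+", 10**7, 10**7 + 10)
    with pytest.raises(ValueError, match="beyond"):
        parclip.annotate_sites([s], annot)


# ---------------------------------------------------------------------------
# Expression enrichment and target sets
# ---------------------------------------------------------------------------

def rpkm_table(annot, value=10.0):
    return pd.DataFrame(
        {"rpkm": value}, index=pd.Index([g.gene_id for g in annot.genes], name="gene_id")
    )


def cds_site(g, rpm):
    mid = (g.cds[0] + g.cds[1]) // 2
    return site(g.chrom, g.strand, mid - 10, mid + 10, rpm=rpm)


def test_log_ratio_zero_and_one(annot):
    g = next(g for g in annot.genes if not g.is_ncRNA)
    rpkm = rpkm_table(annot, 10.0)
    df, excl = parclip.site_expression_enrichment(
        [cds_site(g, 10.0), cds_site(g, 100.0)], rpkm, annot
    )
    assert excl == 0
    assert np.allclose(df["log10_ratio"], [0.0, 1.0])


def test_zero_rpkm_sites_excluded_with_count(annot):
    g = annot.genes[0]
    rpkm = rpkm_table(annot, 0.0)
    df, excl = parclip.site_expression_enrichment([cds_site(g, 5.0)], rpkm, annot)
    assert excl == 1 and df.empty


def test_missing_rpkm_column_rejected(annot):
    bad = pd.DataFrame({"value": [1.0]}, index=["G0001"])
    with pytest.raises(ValueError, match="rpkm"):
        parclip.site_expression_enrichment([], bad, annot)


def test_ttest_power_on_separated_classes(rng):
    """Planted class means 0 and 0.5 (sd 0.3, n=100): the unpaired t-test
    should be overwhelmingly significant."""
    hits = 0
    n_rep = 50
    for _ in range(n_rep):
        g = {
            "a": rng.normal(0.0, 0.3, 100),
            "b": rng.normal(0.5, 0.3, 100),
        }
        res = parclip.unpaired_ttests(g)
        hits += float(res["p"].iloc[0]) < 1e-9
    assert hits / n_rep >= 0.95


def test_target_sets_identical_and_disjoint(annot):
    g1, g2 = annot.genes[0], annot.genes[1]
    a = [cds_site(g1, 5.0)]
    b = [cds_site(g1, 5.0)]
    gene_sets, venn = parclip.target_gene_sets({"a": a, "b": b}, annot)
    assert gene_sets["a"] == gene_sets["b"]
    assert venn["a&b"] == 1 and venn["a"] == 0 and venn["b"] == 0

    gene_sets, venn = parclip.target_gene_sets(
        {"a": [cds_site(g1, 5.0)], "b": [cds_site(g2, 5.0)]}, annot
    )
    assert venn["a&b"] == 0 and venn["a"] == 1 and venn["b"] == 1


def test_venn_counts_match_set_algebra(annot, rng):
    sets = {}
    for ds in ("x", "y", "z"):
        genes = [annot.genes[i] for i in rng.choice(len(annot.genes), 8, replace=False)]
        sets[ds] = [cds_site(g, 2.0) for g in genes]
    gene_sets, venn = parclip.target_gene_sets(sets, annot)
    X, Y, Z = gene_sets["x"], gene_sets["y"], gene_sets["z"]
    assert venn["x"] == len(X - Y - Z)
    assert venn["x&y"] == len((X & Y) - Z)
    assert venn["x&y&z"] == len(X & Y & Z)
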