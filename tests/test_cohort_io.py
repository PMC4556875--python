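"""Cohort parsing, validation, VCF subset reading and report writing."""

import json

import numpy as np
import pandas as pd
import pytest

from strokescore import (
    Cohort,
    CohortValidationError,
    GenotypeParseError,
    association_scan,
    build_score_model,
    chaid_bin,
    make_preset,
    packaged_panel_path,
    read_cohort,
    read_vcf_subset,
    simulate_cohort,
    write_cohort,
    write_report,
)

from conftest import discovery_results, make_cohort

PHENO_HEADER = ("sample_id\tstatus\tsubtype\tsex\thypertension\tdiabetes"
                "\tsmoker\tdyslipidemia\tatrial_fibrillation\n")


def write_tables(tmp_path, genotype_rows, pheno_rows, panel_rows):
    g = tmp_path / "geno.tsv"
    p = tmp_path / "pheno.tsv"
    pl = tmp_path / "panel.tsv"
    g.write_text("\n".join(genotype_rows) + "\n")
    p.write_text(PHENO_HEADER + "\n".join(pheno_rows) + "\n")
    pl.write_text("snp_id\tgene\tchromosome\n" + "\n".join(panel_rows) + "\n")
    return g, p, pl


def default_tables(tmp_path):
    return write_tables(
        tmp_path,
        ["sample_id\trs1\trs2",
         "s1\tAG\tCC",
         "s2\tGG\tCT",
         "s3\tAA\tNN"],
        ["s1\tcase\tcardioembolic\tmale\tyes\tno\tno\tno\tyes",
         "s2\tcase\tlacunar\tfemale\tno\tno\tno\tno\tno",
         "s3\tcontrol\tnone\tfemale\tno\tyes\tno\tno\tno"],
        ["rs1\tNOS3\t7", "rs2\tCRP\t1"],
    )


def test_read_cohort_counts_and_call_rate(tmp_path):
    coh = read_cohort(*default_tables(tmp_path))
    assert coh.n_samples == 3 and coh.n_cases == 2
    assert coh.call_rate("rs2") == pytest.approx(2 / 3)
    assert coh.call_rate("rs1") == 1.0
    # 3 samples x 2 SNPs with one missing call: 5/6 overall
    called = (coh.genotypes.to_numpy() != -1).mean()
    assert called == pytest.approx(5 / 6)
    # minor allele by frequency: rs1 has A x3, G x3 -> tie -> A major
    assert coh.alleles("rs1") == ("A", "G")
    assert list(coh.genotypes["rs1"]) == [1, 2, 0]


def test_genotype_class_count_preservation(tmp_path):
    coh = read_cohort(*default_tables(tmp_path))
    for snp in coh.snp_ids:
        col = coh.genotypes[snp]
        assert sum((col == c).sum() for c in (-1, 0, 1, 2)) == coh.n_samples


def test_control_with_subtype_rejected(tmp_path):
    paths = write_tables(
        tmp_path,
        ["sample_id\trs1", "s1\tAG", "s2\tAA"],
        ["s1\tcase\tcardioembolic\tmale\tno\tno\tno\tno\tno",
         "s2\tcontrol\tcardioembolic\tfemale\tno\tno\tno\tno\tno"],
        ["rs1\tNOS3\t7"],
    )
    with pytest.raises(CohortValidationError, match="subtype"):
        read_cohort(*paths)


def test_malformed_token_names_line(tmp_path):
    paths = write_tables(
        tmp_path,
        ["sample_id\trs1", "s1\tAG", "s2\tAXG"],
        ["s1\tcase\tcardioembolic\tmale\tno\tno\tno\tno\tno",
         "s2\tcontrol\tnone\tfemale\tno\tno\tno\tno\tno"],
        ["rs1\tNOS3\t7"],
    )
    with pytest.raises(GenotypeParseError, match="line 3"):
        read_cohort(*paths)


def test_duplicate_sample_id_rejected(tmp_path):
    paths = write_tables(
        tmp_path,
        ["sample_id\trs1", "s1\tAG", "s1\tAA"],
        ["s1\tcase\tcardioembolic\tmale\tno\tno\tno\tno\tno"],
        ["rs1\tNOS3\t7"],
    )
    with pytest.raises(CohortValidationError, match="duplicate"):
        read_cohort(*paths)


def test_snp_absent_from_panel_rejected(tmp_path):
    paths = write_tables(
        tmp_path,
        ["sample_id\trs1\trs99", "s1\tAG\tCC", "s2\tAA\tCC"],
        ["s1\tcase\tcardioembolic\tmale\tno\tno\tno\tno\tno",
         "s2\tcontrol\tnone\tfemale\tno\tno\tno\tno\tno"],
        ["rs1\tNOS3\t7"],
    )
    with pytest.raises(CohortValidationError, match="rs99"):
        read_cohort(*paths)


def test_sample_id_mismatch_rejected(tmp_path):
    paths = write_tables(
        tmp_path,
        ["sample_id\trs1", "s1\tAG", "sX\tAA"],
        ["s1\tcase\tcardioembolic\tmale\tno\tno\tno\tno\tno",
         "s2\tcontrol\tnone\tfemale\tno\tno\tno\tno\tno"],
        ["rs1\tNOS3\t7"],
    )
    with pytest.raises(CohortValidationError, match="only one table"):
        read_cohort(*paths)


def test_round_trip_identity(tmp_path):
    coh = simulate_cohort(make_preset("discovery_table3"), seed=5)
    paths = write_cohort(coh, tmp_path / "out")
    back = read_cohort(paths["genotypes"], paths["phenotypes"], paths["panel"],
                       name=coh.name)
    assert back.equals(coh)
    assert back.alleles("rs1205") == coh.alleles("rs1205")


def test_packaged_panel_has_68_snps():
    panel = pd.read_csv(packaged_panel_path(), sep="\t")
    assert len(panel) == 68
    assert {"rs1205", "rs1800779", "rs2257073"} <= set(panel["snp_id"])
    assert set(panel.columns) == {"snp_id", "gene", "chromosome"}


# ----------------------------------------------------------------- VCF
VCF_HEADER = (
    "##fileformat=VCFv4.2\n"
    "##contig=<ID=1>\n##contig=<ID=7>\n"
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
)


def write_vcf(tmp_path, body, samples=("S1", "S2", "S3", "S4")):
    path = tmp_path / "t.vcf"
    cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples)
    path.write_text(VCF_HEADER + cols + "\n" + body)
    ph = tmp_path / "ph.tsv"
    rows = []
    for i, s in enumerate(samples):
        status = "case" if i < len(samples) // 2 else "control"
        sub = "cardioembolic" if status == "case" else "none"
        rows.append(f"{s}\t{status}\t{sub}\tmale\tno\tno\tno\tno\tno")
    ph.write_text(PHENO_HEADER + "\n".join(rows) + "\n")
    return path, ph


def test_vcf_gt_mapping_and_major_minor(tmp_path):
    body = (
        "7\t100\trsA\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\t0/0\t0/0\n"
        "1\t200\trsB\tC\tT\t.\t.\t.\tGT\t0/0\t./.\t0/1\t0/0\n"
    )
    vcf, ph = write_vcf(tmp_path, body)
    coh = read_vcf_subset(vcf, ph)
    # alt freq 3/8 for rsA -> ref A stays major: 0/1 het, 1/1 hom-minor
    assert list(coh.genotypes["rsA"]) == [1, 2, 0, 0]
    assert coh.alleles("rsA") == ("A", "G")
    assert list(coh.genotypes["rsB"]) == [0, -1, 1, 0]


def test_vcf_alt_major_flips_coding(tmp_path):
    body = "7\t100\trsA\tA\tG\t.\t.\t.\tGT\t1/1\t1/1\t1/1\t0/1\n"
    vcf, ph = write_vcf(tmp_path, body)
    coh = read_vcf_subset(vcf, ph)
    assert coh.alleles("rsA") == ("G", "A")
    assert list(coh.genotypes["rsA"]) == [0, 0, 0, 1]


def test_vcf_multiallelic_skipped_and_counted(tmp_path):
    body = (
        "7\t100\trsA\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\t0/0\t0/0\n"
        "1\t300\trsC\tG\tT,C\t.\t.\t.\tGT\t0/1\t0/0\t0/0\t0/0\n"
    )
    vcf, ph = write_vcf(tmp_path, body)
    coh = read_vcf_subset(vcf, ph)
    assert coh.meta["skipped_multiallelic"] == 1
    assert coh.snp_ids == ["rsA"]


def test_vcf_and_tsv_agree_downstream(tmp_path):
    """The same calls through VCF and TSV dialects give identical
    association results."""
    body = "7\t100\trs1800779\tA\tG\t.\t.\t.\tGT\t0/1\t1/1\t0/0\t0/1\n"
    vcf, ph = write_vcf(tmp_path, body)
    from_vcf = read_vcf_subset(vcf, ph)
    g, p, pl = write_tables(
        tmp_path,
        ["sample_id\trs1800779", "S1\tAG", "S2\tGG", "S3\tAA", "S4\tAG"],
        ["S1\tcase\tcardioembolic\tmale\tno\tno\tno\tno\tno",
         "S2\tcase\tcardioembolic\tmale\tno\tno\tno\tno\tno",
         "S3\tcontrol\tnone\tmale\tno\tno\tno\tno\tno",
         "S4\tcontrol\tnone\tmale\tno\tno\tno\tno\tno"],
        ["rs1800779\tNOS3\t7"],
    )
    from_tsv = read_cohort(g, p, pl)
    res_v = association_scan(from_vcf, contrasts=["cardioembolic"], policy="all")
    res_t = association_scan(from_tsv, contrasts=["cardioembolic"], policy="all")
    for rv, rt in zip(res_v, res_t):
        assert rv.table.cells == rt.table.cells
        assert rv.p == pytest.approx(rt.p)


# --------------------------------------------------------------- report
def test_write_report_formula_and_determinism(tmp_path):
    results = discovery_results()
    model = build_score_model(results)
    rng = np.random.default_rng(1)
    scores = rng.choice([0, 1.5, 2.2, 3.7, 5.8], size=300)
    labels = rng.random(300) < 0.3 + 0.1 * scores
    strat = chaid_bin(scores, labels)
    paths1 = write_report(results, model, strat, tmp_path / "a", config={"seed": 1})
    paths2 = write_report(results, model, strat, tmp_path / "b", config={"seed": 1})

    payload = json.loads(paths1["score_model"].read_text())
    assert payload["formula"] == (
        "1.5*rs1205[CT/TT] + 2.2*rs1800779[GG] + 2.1*rs2257073[CT/CC]"
    )
    assert payload["max_score"] == 5.8
    strat_payload = json.loads(paths1["stratification"].read_text())
    assert len(strat_payload["groups"]) == len(strat.groups)

    for key in ("results", "score_model", "stratification"):
        assert paths1[key].read_bytes() == paths2[key].read_bytes()
    log1 = [l for l in paths1["log"].read_text().splitlines()
            if not l.startswith("# generated")]
    log2 = [l for l in paths2["log"].read_text().splitlines()
            if not l.startswith("# generated")]
    assert log1 == log2


def test_write_report_empty_results_header_only(tmp_path):
    paths = write_report([], None, None, tmp_path)
    lines = paths["results"].read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("snp_id\tgene\tcontrast")
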