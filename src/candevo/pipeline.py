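"""Orchestration: run all analysis stages over on-disk inputs, emit a report.

A :class:`RunConfig` names the inputs (ORF FASTA, Newick tree, UTR FASTA,
exon map, reporter CSV — each optional) and the analysis parameters.
:func:`run` executes the enabled stages in dependency order, writes each
stage's tables as TSV under the output directory, and assembles a markdown
report with a provenance block (config hash, seed, package version).  All
randomness flows from the single configured seed via fixed per-stage
substreams, so identical configs produce byte-identical outputs.

:func:`make_fixture` writes a complete synthetic dataset (with ground truth)
in the same formats the pipeline reads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from . import ancestry, regulatory, reporter, selection
from .seqdata import (
    CodonAlignment,
    ExonMap,
    TimedTree,
    UTRAlignment,
    read_exon_map,
    read_fasta_alignment,
    read_newick_timed,
    translate,
    write_exon_map,
    write_fasta_alignment,
)
from .synthetic import SimConfig, simulate_orf, simulate_reporter, simulate_tree, simulate_utr

__all__ = ["RunConfig", "AnalysisReport", "run", "make_fixture", "PRESETS"]

# per-stage seed substream offsets
_SUB_NEUTRALITY, _SUB_BOOTSTRAP = 101, 103


@dataclass
class RunConfig:
    """Inputs and parameters for a pipeline run."""

    out_dir: str
    orf_fasta: str | None = None
    tree_newick: str | None = None
    utr_fasta: str | None = None
    exon_bed: str | None = None
    reporter_csv: str | None = None
    seed: int = 0
    bootstrap_B: int = 1000
    window: int = 20
    step: int = 5
    lmin: int = 50
    allow_overlap: bool = True
    run_per_site: bool = False

    def enabled_stages(self) -> list[str]:
        stages = []
        if self.orf_fasta and self.tree_newick:
            stages += ["census", "neutrality", "saturation"]
            if self.exon_bed:
                stages.append("exon_enrichment")
        if self.utr_fasta:
            stages += ["shadow", "motifs"]
        if self.reporter_csv:
            stages.append("reporter")
        return stages

    def validate(self) -> None:
        if not self.enabled_stages():
            raise ValueError(
                "no analysis enabled: provide an ORF+tree, a UTR alignment, or a reporter table"
            )
        for name in ("orf_fasta", "tree_newick", "utr_fasta", "exon_bed", "reporter_csv"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class AnalysisReport:
    """Collected per-stage results plus the rendered markdown report."""

    sections: dict = field(default_factory=dict)
    markdown: str = ""
    out_dir: str = ""


def _stage_seed(cfg: RunConfig, offset: int) -> int:
    return int((cfg.seed * 1_000_003 + offset) % (2**31 - 1))


def run(config: RunConfig) -> AnalysisReport:
    """Execute all enabled stages and write artifacts + report.md."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = AnalysisReport(out_dir=str(out))
    md = ["# Candidate-gene evolution analysis report", ""]
    md += [
        "## Provenance",
        "",
        f"- config hash: `{config.config_hash()}`",
        f"- seed: {config.seed}",
        f"- candevo version: {__version__}",
        f"- stages: {', '.join(config.enabled_stages())}",
        "",
    ]

    orf = tree = prot = None
    if config.orf_fasta and config.tree_newick:
        orf = read_fasta_alignment(config.orf_fasta, expect_codon=True)
        tree = read_newick_timed(config.tree_newick)
        missing = set(orf.taxa) - set(tree.leaf_labels)
        if missing:
            raise ValueError(f"[census] alignment taxa absent from tree: {sorted(missing)}")
        prot = translate(orf)

        cen = ancestry.census(prot, tree)
        pd.DataFrame(
            {"site": np.arange(len(cen.site_counts)), "changes": cen.site_counts}
        ).to_csv(out / "census_sites.tsv", sep="\t", index=False)
        report.sections["census"] = cen
        md += [
            "## Substitution census",
            "",
            f"- variable sites V = {cen.V}",
            f"- recurrent sites M = {cen.M}",
            f"- total inferred substitutions T = {cen.T}",
            f"- mean changes per variable site = {cen.mean_per_variable:.2f}"
            + (" (degenerate: no variation)" if cen.degenerate else ""),
            "",
        ]

        conv = ancestry.convergence_report(prot, tree, cen)
        with open(out / "convergence.tsv", "w") as fh:
            fh.write("site\tstate\tlineages\n")
            for c in conv:
                fh.write(f"{c.site}\t{c.state}\t{','.join(c.carriers)}\n")
        report.sections["convergence"] = conv

        neut = selection.neutrality_test(
            orf, B=config.bootstrap_B, seed=_stage_seed(config, _SUB_NEUTRALITY)
        )
        report.sections["neutrality"] = neut
        md += [
            "## Neutrality test",
            "",
            f"- mean dN = {neut.mean_dN:.4f}, mean dS = {neut.mean_dS:.4f}",
            "- degenerate (no variation): Z undefined"
            if neut.degenerate
            else f"- Z = {neut.z:.2f} (bootstrap SE {neut.se:.4g}, B = {neut.B}), "
            f"two-tailed P = {neut.p_two_tailed:.4g}",
            "",
        ]

        if config.run_per_site:
            sites = selection.per_site_selection(orf, tree)
            pd.DataFrame([asdict(s) for s in sites]).to_csv(
                out / "per_site_selection.tsv", sep="\t", index=False
            )
            report.sections["per_site_selection"] = sites

        dm_nt = selection.pairwise_differences(orf, level="nt")
        dm_aa = selection.pairwise_differences(prot, level="aa")
        dm_nt.to_data_frame().to_csv(out / "distances_nt.tsv", sep="\t")
        dm_aa.to_data_frame().to_csv(out / "distances_aa.tsv", sep="\t")
        sat_nt = selection.saturation_fit(dm_nt, tree)
        sat_aa = selection.saturation_fit(dm_aa, tree)
        report.sections["saturation"] = {"nt": sat_nt, "aa": sat_aa}
        md += [
            "## Saturation regression (differences vs t_mrca)",
            "",
            f"- nucleotide: slope {sat_nt.slope:.3f}, R² = {sat_nt.r_squared:.3f}",
            f"- amino acid: slope {sat_aa.slope:.3f}, R² = {sat_aa.r_squared:.3f}",
            "",
        ]

        if config.exon_bed:
            exon_map = read_exon_map(config.exon_bed)
            enr = ancestry.exon_binomial(cen.site_counts, exon_map)
            pd.DataFrame([asdict(e) for e in enr]).to_csv(
                out / "exon_enrichment.tsv", sep="\t", index=False
            )
            report.sections["exon_enrichment"] = enr
            md += ["## Exon enrichment", ""]
            for e in enr:
                md.append(
                    f"- {e.exon}: {e.observed}/{e.total} replacements, "
                    f"L_e = {e.length}, P_cum = {e.p_cum:.3g}"
                )
            md.append("")

    if config.utr_fasta:
        utr = read_fasta_alignment(config.utr_fasta, expect_codon=False)
        prof = regulatory.divergence_profile(utr, config.window, config.step)
        pd.DataFrame({"start": prof.starts, "divergence": prof.values}).to_csv(
            out / "divergence_profile.tsv", sep="\t", index=False
        )
        report.sections["divergence_profile"] = prof

        islands = []
        if orf is not None:
            orf_cols = regulatory.variant_indicator(orf)
            utr_cols = regulatory.variant_indicator(utr)
            try:
                hmm = regulatory.calibrate_hmm(orf_cols, utr_cols, lmin=config.lmin)
                islands = regulatory.segment_islands(utr, hmm)
                report.sections["islands"] = islands
            except regulatory.CalibrationError as err:
                report.sections["islands"] = err
                md += ["## Conserved islands", "", f"- calibration failed: {err}", ""]
        if "islands" in report.sections and not isinstance(report.sections["islands"], Exception):
            with open(out / "islands.bed", "w") as fh:
                for i, isl in enumerate(islands):
                    fh.write(f"utr\t{isl.start}\t{isl.end}\tisland{i}\t{isl.mean_divergence:.4f}\n")
            md += ["## Conserved islands", ""]
            if islands:
                for isl in islands:
                    md.append(
                        f"- [{isl.start}, {isl.end}) length {isl.length} nt, "
                        f"mean divergence {isl.mean_divergence:.3f}"
                    )
            else:
                md.append("- none at the configured minimum length")
            md.append("")

        mat = regulatory.motif_matrix(utr, allow_overlap=config.allow_overlap)
        mat.presence.to_csv(out / "motif_matrix.tsv", sep="\t")
        report.sections["motifs"] = mat
        md += ["## Motif loci (Musashi binding elements)", ""]
        if mat.loci:
            for (a, b), f in zip(mat.loci, mat.frequencies):
                md.append(f"- locus [{a}, {b}): present in {100 * f:.0f}% of taxa")
        else:
            md.append("- no motif hits")
        md.append("")

    if config.reporter_csv:
        table = reporter.load_fluorescence(config.reporter_csv)
        per_line = reporter.ratios(table)
        kw = reporter.kruskal_wallis(per_line)
        w, p_norm = reporter.normality_check(np.concatenate(list(per_line.values())))
        loo = reporter.leave_one_group_out(per_line) if len(per_line) >= 3 else {}
        rows = [{"dropped": "none", "H": kw.h, "df": kw.df, "P": kw.p}]
        rows += [{"dropped": k, "H": r.h, "df": r.df, "P": r.p} for k, r in loo.items()]
        pd.DataFrame(rows).to_csv(out / "reporter_stats.tsv", sep="\t", index=False)
        report.sections["reporter"] = {"kw": kw, "normality": (w, p_norm), "loo": loo}
        md += [
            "## Reporter assay",
            "",
            f"- Shapiro-Wilk on pooled ratios: W = {w:.3f}, P = {p_norm:.3g}",
            f"- Kruskal-Wallis: H = {kw.h:.2f}, df = {kw.df}, P = {kw.p:.3g}",
        ]
        for k, r in loo.items():
            md.append(f"- drop '{k}': H = {r.h:.2f}, P = {r.p:.3g}")
        md.append("")

    report.markdown = "\n".join(md)
    (out / "report.md").write_text(report.markdown)
    return report


# ---------------------------------------------------------------------------
# Fixture generation

PRESETS: dict[str, dict] = {
    "tiny": dict(n_taxa=6, n_codons=60, utr_length=300, islands=((60, 160),),
                 motif_positions=(90, 200), motif_presence=(1.0, 0.5),
                 motif_run_lengths=(1, 2)),
    "small": dict(n_taxa=12, n_codons=350, utr_length=800),
}


def make_fixture(out_dir: str | Path, seed: int = 0, preset: str = "small") -> dict[str, Path]:
    """Write a synthetic dataset (FASTA/Newick/BED/CSV + truth JSON) to disk."""
    if preset not in PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(PRESETS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = SimConfig(seed=seed, **PRESETS[preset])
    tree = simulate_tree(cfg)
    orf, _, orf_truth = simulate_orf(cfg, tree)
    utr, utr_truth = simulate_utr(cfg, tree)
    table = simulate_reporter(cfg)
    utr_truth.reporter_group_means = dict(cfg.reporter_group_means)

    paths = {
        "orf": out / "orf.fasta",
        "tree": out / "tree.nwk",
        "utr": out / "utr.fasta",
        "exons": out / "exons.bed",
        "reporter": out / "reporter.csv",
        "orf_truth": out / "orf_truth.json",
        "utr_truth": out / "utr_truth.json",
    }
    write_fasta_alignment(orf, paths["orf"])
    tree.write(paths["tree"])
    write_fasta_alignment(utr, paths["utr"])
    # three exons splitting the protein, emulating a multi-exon locus
    n_aa = cfg.n_codons
    b1, b2 = n_aa // 3, 2 * n_aa // 3
    from .seqdata import ExonRecord

    write_exon_map(
        ExonMap((ExonRecord("exon1", 0, b1), ExonRecord("exon2", b1, b2),
                 ExonRecord("exon3", b2, n_aa))),
        paths["exons"],
    )
    table.to_csv(paths["reporter"], index=False)
    orf_truth.to_json(paths["orf_truth"])
    utr_truth.to_json(paths["utr_truth"])
    return paths
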