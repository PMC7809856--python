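"""End-to-end pipeline over synthetic data, plus report arithmetic.

``pipeline_run`` chains simulate -> mean-normalize -> protein
quantification -> site quantification -> crosstalk -> motif discovery ->
conservation -> enrichment, writes every stage's TSV, and returns a summary
in the bookkeeping style of TMT PTM studies (identified / quantified /
up / down counts, enrichment efficiency, single-site proportion). Stage
failures abort with the stage name and remove partial outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import conservation as cons
from . import enrichment as enr
from . import io as kio
from . import motifs as mot
from . import quantify as qn
from . import synthetic as syn

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Report arithmetic
# ---------------------------------------------------------------------------

def enrichment_efficiency(n_modified_peptides: int, n_total_peptides: int) -> float:
    """Percentage of enriched peptides carrying the modification (1 decimal)."""
    if n_total_peptides <= 0:
        raise ValueError("total peptide count must be positive")
    return round(100.0 * n_modified_peptides / n_total_peptides, 1)


def single_site_percentage(n_single_site_proteins: int, n_modified_proteins: int) -> float:
    """Percentage of modified proteins carrying exactly one site (2 decimals)."""
    if n_modified_proteins <= 0:
        raise ValueError("modified protein count must be positive")
    return round(100.0 * n_single_site_proteins / n_modified_proteins, 2)


def site_multiplicity(sites: list[tuple[str, int]]) -> dict[int, int]:
    """Histogram: number of proteins carrying exactly k sites."""
    per_prot: dict[str, int] = {}
    for pid, _ in sites:
        per_prot[pid] = per_prot.get(pid, 0) + 1
    hist: dict[int, int] = {}
    for count in per_prot.values():
        hist[count] = hist.get(count, 0) + 1
    return hist


# ---------------------------------------------------------------------------
# Full synthetic run
# ---------------------------------------------------------------------------

def pipeline_run(config: kio.RunConfig) -> dict:
    """Run the whole workflow on freshly simulated data; return the summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    chash = config.hash()
    stage = "setup"

    def save(df: pd.DataFrame, name: str) -> None:
        path = out / name
        kio.write_table(df, path, chash)
        written.append(path)

    try:
        seeds = np.random.SeedSequence(config.seed).generate_state(6) % (2**31)
        design = syn.ChannelDesign.default()
        qconf = qn.QuantConfig(
            fc_threshold=config.fc_threshold, alpha=config.alpha,
            loc_prob_min=config.loc_prob_min,
            min_values_per_group=config.min_values_per_group,
            use_pvalue=config.use_pvalue, welch=config.welch,
        )

        stage = "simulate"
        proteome = syn.generate_proteome(
            config.n_proteins, (100, 600), seed=int(seeds[0])
        )
        motif_specs = [syn.MotifSpec(((-1, "F"), (1, "E")), 0.3)]
        proteome, sites, truth = syn.plant_sites_and_motifs(
            proteome, config.site_fraction, motif_specs, seed=int(seeds[1])
        )
        syn.assign_effects(
            truth, proteome, sites, anticorrelated=True, seed=int(seeds[2])
        )
        peptides = syn.digest_proteome(proteome)
        pep_df, site_df = syn.simulate_intensities(
            proteome, peptides, sites, truth, design,
            noise_sd=config.noise_sd, missing_rate=config.missing_rate,
            seed=int(seeds[3]),
        )
        kio.write_fasta(proteome, out / "proteome.fasta")
        written.append(out / "proteome.fasta")
        save(pep_df, "peptides.tsv")
        save(site_df, "sites.tsv")
        save(
            pd.DataFrame(
                [{"protein_id": k, "log2_effect": v}
                 for k, v in sorted(truth.protein_effects.items())]
            ),
            "truth_proteins.tsv",
        )
        save(
            pd.DataFrame(
                [{"protein_id": k[0], "position": k[1], "log2_site_effect": v}
                 for k, v in sorted(truth.site_effects.items())]
            ),
            "truth_sites.tsv",
        )

        stage = "normalize"
        pep_norm = qn.mean_normalize(pep_df, design)
        site_norm = qn.mean_normalize(site_df, design, reference=pep_df)

        stage = "quantify_proteins"
        prot_results = qn.quantify_proteins(pep_norm, design, qconf)
        save(qn.protein_results_frame(prot_results), "protein_results.tsv")

        stage = "quantify_sites"
        site_results = qn.quantify_sites(
            site_norm, prot_results, design, qconf, proteins=proteome
        )
        save(qn.site_results_frame(site_results), "site_results.tsv")

        stage = "crosstalk"
        records, xt_counts = qn.crosstalk(prot_results, site_results)
        save(qn.crosstalk_frame(records), "crosstalk.tsv")

        stage = "motifs"
        localized = [
            (s.protein_id, s.position) for s in site_results
        ]
        fg = mot.extract_windows(proteome, localized)
        bg = mot.background_windows(proteome)
        motif_models = mot.find_motifs(
            fg, bg, p_threshold=config.motif_p_threshold,
            min_occurrences=config.motif_min_occurrences,
            max_motifs=config.motif_max,
        )
        save(mot.motifs_frame(motif_models), "motifs.tsv")
        heat = mot.enrichment_matrix(fg, bg)
        kio.write_table(
            heat.reset_index(names="offset"), out / "heatmap.tsv", chash
        )
        written.append(out / "heatmap.tsv")

        stage = "conservation"
        species = [f"species{i + 1}" for i in range(config.n_species)]
        orthologs, ctruth = syn.generate_orthologs(
            proteome, species, config.substitution_rate, sites,
            config.kcr_keep, config.control_keep, seed=int(seeds[4]),
        )
        scheme = cons.ScoringScheme(
            gap_open=config.gap_open, gap_extend=config.gap_extend,
            min_rbh_score=config.min_rbh_score,
        )
        cons_rows, orth_rows = [], []
        for sp in species:
            summary, pairs = cons.conservation_summary(
                proteome, orthologs[sp], sp, sites, scheme
            )
            cons_rows.append(
                {"species": sp, "kcr_conserved": summary.kcr_conserved,
                 "kcr_total": summary.kcr_total,
                 "ctrl_conserved": summary.ctrl_conserved,
                 "ctrl_total": summary.ctrl_total,
                 "kcr_pct": summary.kcr_pct, "ctrl_pct": summary.ctrl_pct,
                 "fisher_p": summary.fisher_p}
            )
            orth_rows.extend(
                {"query_id": p.query_id, "species": p.subject_species,
                 "subject_id": p.subject_id, "forward_score": p.forward_score,
                 "reverse_score": p.reverse_score}
                for p in pairs
            )
        save(pd.DataFrame(orth_rows), "orthologs.tsv")
        save(pd.DataFrame(cons_rows), "conservation.tsv")

        stage = "enrichment"
        rng = np.random.default_rng(int(seeds[5]))
        terms: dict[str, set[str]] = {f"TERM{i:02d}": set() for i in range(10)}
        for prot in proteome:
            for t in rng.choice(sorted(terms), size=int(rng.integers(1, 4)),
                                replace=False):
                terms[t].add(prot.protein_id)
        ann = enr.AnnotationMap({t: s for t, s in terms.items() if s})
        background = {r.protein_id for r in prot_results if r.ratio is not None}
        differential = {
            r.protein_id for r in prot_results if r.reg_class in (qn.UP, qn.DOWN)
        }
        enr_results = enr.enrich(differential, background, ann)
        save(enr.enrichment_frame(enr_results), "enrichment.tsv")

        stage = "report"
        n_pep, n_mod = len(pep_df), len(site_df)
        per_prot = site_multiplicity(sites)
        n_modified_proteins = sum(per_prot.values())
        summary = {
            "n_proteins": len(proteome),
            "n_proteins_quantified": sum(
                1 for r in prot_results if r.ratio is not None
            ),
            "n_proteins_up": sum(1 for r in prot_results if r.reg_class == qn.UP),
            "n_proteins_down": sum(1 for r in prot_results if r.reg_class == qn.DOWN),
            "n_sites_identified": len(site_df),
            "n_sites_localized": len(site_results),
            "n_sites_quantified": sum(
                1 for s in site_results if s.raw_ratio is not None
            ),
            "n_sites_normalized": sum(1 for s in site_results if s.normalized),
            "n_sites_up": sum(1 for s in site_results if s.reg_class == qn.UP),
            "n_sites_down": sum(1 for s in site_results if s.reg_class == qn.DOWN),
            "enrichment_efficiency_pct": enrichment_efficiency(n_mod, n_pep + n_mod),
            "single_site_pct": single_site_percentage(
                per_prot.get(1, 0), n_modified_proteins
            ) if n_modified_proteins else None,
            "crosstalk": xt_counts,
            "motifs": [m.name for m in motif_models],
            "conservation": cons_rows,
        }
        config.to_file(out / "config.txt")
        written.append(out / "config.txt")
        with open(out / "summary.txt", "w") as fh:
            for key, value in summary.items():
                fh.write(f"{key}\t{value}\n")
        written.append(out / "summary.txt")
        log.info("pipeline complete: %s", summary)
        return summary
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
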