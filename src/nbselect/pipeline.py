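"""End-to-end orchestration of the analysis stages.

Each stage is a function over a shared working directory: ``simulate``
writes the standard-format inputs under ``<workdir>/inputs``, later stages
read only files written by earlier ones (stage isolation), and ``report``
aggregates the headline numbers.  Outputs carry no timestamps, so a rerun
with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import InputError
from . import genome_io as gio
from .genome_io import GeneModel, INGROUPS, RegionSet
from . import popstats as ps
from . import selection_scan as scan
from . import coding_effects as ce
from . import family_analysis as fam
from . import qtl_colocation as qtl
from . import synthetic_data as synth

#: score-per-base prefilter below which a pair cannot reach the 70%/70%
#: identity-coverage family threshold (see docs/methods.md)
_SCORE_PREFILTER = 0.07


def _inputs(workdir: Path) -> Path:
    return Path(workdir) / "inputs"


def _results(workdir: Path) -> Path:
    p = Path(workdir) / "results"
    p.mkdir(parents=True, exist_ok=True)
    return p


def load_config(path: str | Path | None, seed: int | None = None) -> synth.SimulationConfig:
    import yaml

    data: dict = {}
    if path is not None:
        if not Path(path).exists():
            raise InputError(f"config file not found: {path}")
        data = yaml.safe_load(Path(path).read_text()) or {}
    if seed is not None:
        data["seed"] = seed
    if "seed" not in data:
        raise InputError("a seed is required (config key 'seed' or --seed)")
    for key in ("cluster_size_range", "cluster_spacing", "qtl_halfwidth_cm", "qtl_traits"):
        if key in data and isinstance(data[key], list):
            data[key] = tuple(data[key])
    try:
        return synth.SimulationConfig(**data)
    except TypeError as exc:
        raise InputError(f"bad config: {exc}") from exc


def stage_simulate(config: synth.SimulationConfig, workdir: str | Path) -> None:
    """Generate the synthetic panel and write every standard-format input."""
    inp = _inputs(workdir)
    inp.mkdir(parents=True, exist_ok=True)
    annotation = synth.simulate_annotation(config)
    panels, _ = synth.simulate_panel(config, annotation)
    coding = synth.simulate_coding_variants(config, annotation)
    panels = synth.merge_coding_variants(panels, coding)
    truth = annotation.truth
    gio.write_variant_panel(panels, inp / "panel.vcf", annotation.chrom_lengths)
    gio.write_groups_table(config.sample_groups, inp / "groups.tsv")
    gio.write_gene_models(annotation.genes, inp / "genes.gff3")
    gio.write_class_table(annotation.genes, inp / "classes.tsv")
    gio.write_fasta(dict(sorted(annotation.cds_seqs.items())), inp / "cds.fasta")
    gio.write_fasta(dict(sorted(annotation.region_seqs.items())), inp / "regions.fasta")
    pd.DataFrame(
        [(m.marker_id, m.chrom, m.cm, m.bp) for m in annotation.markers],
        columns=["marker", "chrom", "cm", "bp"],
    ).to_csv(inp / "markers.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(q.qtl_id, q.trait, q.chrom, q.cm_start, q.cm_end, q.source) for q in annotation.qtls],
        columns=["qtl_id", "trait", "chrom", "cm_start", "cm_end", "study"],
    ).to_csv(inp / "qtl.tsv", sep="\t", index=False)
    coding.depth.to_csv(inp / "depth.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(annotation.chrom_lengths.items()), columns=["chrom", "length"]
    ).to_csv(inp / "chrom_lengths.tsv", sep="\t", index=False)
    rows = []
    for g in annotation.genes:
        gid = g.gene_id
        rows.append(
            {
                "gene_id": gid,
                "selection_class": truth.selection_class.get(gid, "neutral"),
                "phase": truth.phase.get(gid, "none"),
                "cluster_id": truth.cluster_id.get(gid) or "",
                "family_id": truth.family_id.get(gid, ""),
                "pseudogene": int(truth.pseudogene.get(gid, False)),
                "qtl_target": int(gid in truth.qtl_target_genes),
            }
        )
    pd.DataFrame(rows).sort_values("gene_id").to_csv(
        inp / "truth_labels.tsv", sep="\t", index=False
    )
    cfg = asdict(config)
    (inp / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True, default=list))


def _load_genes(workdir: Path) -> list[GeneModel]:
    inp = _inputs(workdir)
    return gio.read_gene_models(inp / "genes.gff3", inp / "classes.tsv")


def _load_panels(workdir: Path, strict_het: bool = False):
    inp = _inputs(workdir)
    return gio.read_variant_panel(inp / "panel.vcf", inp / "groups.tsv", strict_het)


def _load_chrom_lengths(workdir: Path) -> dict[str, int]:
    df = pd.read_csv(_inputs(workdir) / "chrom_lengths.tsv", sep="\t")
    return dict(zip(df["chrom"], df["length"]))


def stage_stats(workdir: str | Path, strict_het: bool = False) -> None:
    """Per-gene summary statistics over gene spans and padded windows."""
    workdir = Path(workdir)
    genes = [g for g in _load_genes(workdir) if g.species == "sorghum"]
    panels = _load_panels(workdir, strict_het)
    clens = _load_chrom_lengths(workdir)
    tables = {}
    for window in ("gene_span", "gene_pad10kb"):
        gs, fst = ps.windowed_stats(panels, genes, window, chrom_lengths=clens)
        tables[f"gene_stats_{window}"] = pd.DataFrame(
            [
                (s.gene_id, s.group, s.n_samples, s.n_sites, s.s, s.theta_pi, s.theta_w, s.tajima_d)
                for s in gs
            ],
            columns=["gene_id", "group", "n", "n_sites", "s", "theta_pi", "theta_w", "tajima_d"],
        )
        tables[f"fst_{window}"] = pd.DataFrame(
            [(f.gene_id, f.comparison, f.fst) for f in fst],
            columns=["gene_id", "comparison", "fst"],
        )
    gio.write_results_tables(tables, _results(workdir))


def _read_stats(workdir: Path, window: str = "gene_span"):
    res = _results(workdir)
    sdf = pd.read_csv(res / f"gene_stats_{window}.tsv", sep="\t")
    fdf = pd.read_csv(res / f"fst_{window}.tsv", sep="\t")
    gs = [
        ps.GeneStats(r.gene_id, r.group, int(r.n), int(r.n_sites), int(r.s),
                     float(r.theta_pi), float(r.theta_w), float(r.tajima_d))
        for r in sdf.itertuples(index=False)
    ]
    fst = [ps.FstRecord(r.gene_id, r.comparison, float(r.fst)) for r in fdf.itertuples(index=False)]
    return gs, fst


def stage_scan(workdir: str | Path, n_hka_neutral: int = 38) -> None:
    """Selection classification, invariance, HKA validation, flank profile."""
    workdir = Path(workdir)
    genes = [g for g in _load_genes(workdir) if g.species == "sorghum"]
    panels = _load_panels(workdir)
    gs, fst = _read_stats(workdir)
    tails = scan.build_tail_sets(gs, fst)
    calls = scan.classify_selection(gs, fst, tails)
    res = _results(workdir)
    call_df = pd.DataFrame(
        [
            (
                c.gene_id,
                c.call,
                c.phase,
                ";".join(c.evidence.get("balancing_groups", ())),
            )
            for c in calls
        ],
        columns=["gene_id", "call", "phase", "balancing_groups"],
    )
    inv = scan.invariance_report(panels, genes)
    call_df["invariance"] = call_df["gene_id"].map(inv)
    # HKA: purifying candidates (and balancing candidates) against a fixed
    # panel of neutral loci, mirroring the 17+38 / 23+38 locus design
    call_of = dict(zip(call_df["gene_id"], call_df["call"]))
    s_all = {}
    for g in genes:
        panel = panels.get(g.chrom)
        win = panel.window(g.start, g.end) if panel is not None else None
        count = 0
        if win is not None:
            for grp in INGROUPS:
                count += ps.segregating_sites(win, grp)
        s_all[g.gene_id] = count
    d_all = scan.hka_divergence_counts(panels, genes)
    nbs_ids = {g.gene_id for g in genes if g.is_nbs}
    neutral_pool = sorted(
        gid for gid, c in call_of.items()
        if c == "neutral" and gid not in nbs_ids and s_all[gid] > 0
    )[:n_hka_neutral]
    n_ingroup = sum(
        1 for s, grp in next(iter(panels.values())).groups.items() if grp != "outgroup"
    )
    hka_rows = []
    for analysis in ("purifying", "balancing"):
        selected = sorted(
            gid for gid, c in call_of.items()
            if c == analysis and gid in nbs_ids and s_all[gid] > 0
        )
        if not selected or not neutral_pool:
            continue
        loci = {gid: s_all[gid] for gid in selected + neutral_pool}
        divs = {gid: d_all[gid] for gid in loci}
        result = scan.hka_fit(loci, divs, n_ingroup, selected=set(selected))
        hka_rows.append(
            {
                "analysis": analysis,
                "n_selected": len(selected),
                "n_neutral": len(neutral_pool),
                "lnl_neutral": result.lnl_neutral,
                "lnl_selection": result.lnl_selection,
                "lrt": result.lrt,
                "df": result.df,
                "p_value": result.p_value,
                "t_hat": result.t_hat,
                "mean_k_hat": float(np.mean(list(result.k_hat.values()))),
                "converged": result.converged,
            }
        )
    focal = [g for g in genes if g.is_nbs]
    profiles, enrichment = scan.sweep_flank_profile(focal, genes, gs)
    flank_df = pd.DataFrame(
        [
            {
                "gene_id": p.gene_id,
                "n_flank_genes": len(p.flank_genes),
                **{f"mean_flank_pi_{g}": p.mean_flank_pi[g] for g in p.mean_flank_pi},
            }
            for p in profiles
        ]
    )
    enr_df = pd.DataFrame(
        [(g, chi, p) for g, (chi, p) in enrichment.items()],
        columns=["group", "chi2", "p_value"],
    )
    gio.write_results_tables(
        {
            "selection_calls": call_df,
            "hka_results": pd.DataFrame(hka_rows),
            "flank_profile": flank_df,
            "flank_enrichment": enr_df,
        },
        res,
    )


def stage_families(workdir: str | Path) -> None:
    """Clusters, pairwise metrics, families, ancestry, NJ tree, pair Ka/Ks."""
    workdir = Path(workdir)
    inp = _inputs(workdir)
    res = _results(workdir)
    genes = _load_genes(workdir)
    cds = gio.read_fasta(inp / "cds.fasta")
    nbs = [g for g in genes if g.is_nbs and g.gene_id in cds]
    clusters = fam.detect_clusters_genome([g for g in nbs if g.species == "sorghum"])
    gio.write_bed(
        RegionSet(
            "nbs_clusters",
            [
                (
                    next(g.chrom for g in nbs if g.gene_id == c.members[0]),
                    min(g.start for g in nbs if g.gene_id in c.members),
                    max(g.end for g in nbs if g.gene_id in c.members),
                )
                for c in clusters
            ],
        ),
        res / "clusters.bed",
    )
    # all-vs-all metrics with a score prefilter: pairs whose per-base score
    # cannot reach the 70/70 threshold are recorded as non-edges
    ids = sorted(g.gene_id for g in nbs)
    metrics: dict[tuple[str, str], tuple[float, float]] = {}
    rows = []
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            sa, sb = cds[a], cds[b]
            score = fam.alignment_score(sa, sb)
            if score < _SCORE_PREFILTER * min(len(sa), len(sb)):
                rows.append((a, b, score, math.nan, math.nan, 0))
                continue
            ident, cov = fam.pairwise_identity_coverage(sa, sb)
            metrics[(a, b)] = (ident, cov)
            rows.append((a, b, score, ident, cov, int(ident >= 0.7 and cov >= 0.7)))
    pair_df = pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "score", "identity", "coverage", "edge"]
    )
    assignments = fam.build_families(nbs, metrics)
    fam_df = pd.DataFrame(
        [
            (a.gene_id, a.clade_id, a.family_size, a.ancestry, a.paralog_status)
            for a in assignments
        ],
        columns=["gene_id", "clade_id", "family_size", "ancestry", "paralog_status"],
    )
    # NJ tree over NBS-domain p-distances
    with_domain = [g for g in nbs if g.nbs_domain is not None]
    tree_newick = ""
    if len(with_domain) >= 3:
        doms = {
            g.gene_id: cds[g.gene_id][g.nbs_domain[0] : g.nbs_domain[1]]
            for g in with_domain
        }
        tids = sorted(doms)
        dm = np.zeros((len(tids), len(tids)))
        for i, a in enumerate(tids):
            for j in range(i + 1, len(tids)):
                ident, _ = fam.pairwise_identity_coverage(doms[a], doms[tids[j]])
                dm[i, j] = dm[j, i] = 1.0 - ident
        tree = fam.nj_tree(dm, tids)
        tree_newick = tree.to_newick()
        (res / "tree.newick").write_text(tree_newick + "\n")
    # Ka/Ks and 4DTv for same-family sorghum pairs
    fam_of = dict(zip(fam_df["gene_id"], fam_df["clade_id"]))
    sorghum_ids = {g.gene_id for g in nbs if g.species == "sorghum"}
    kaks_rows = []
    for (a, b) in metrics:
        if a in sorghum_ids and b in sorghum_ids and fam_of.get(a) == fam_of.get(b):
            try:
                rec = ce.ng86_kaks(cds[a], cds[b], (a, b))
            except InputError:
                continue
            tv, recent = ce.fourfold_tv(cds[a], cds[b])
            kaks_rows.append((a, b, rec.ka, rec.ks, rec.ratio, tv, int(recent)))
    kaks_df = pd.DataFrame(
        kaks_rows,
        columns=["gene_a", "gene_b", "ka", "ks", "ratio", "fourfold_tv", "recent_duplicate"],
    )
    # cluster membership fractions stratified by selection call
    calls = pd.read_csv(res / "selection_calls.tsv", sep="\t")
    strata = dict(zip(calls["gene_id"], calls["call"]))
    nbs_strata = {g: c for g, c in strata.items() if g in sorghum_ids}
    frac = fam.clustered_fraction(clusters, nbs_strata)
    frac_df = pd.DataFrame(
        [(k, v if v is not None else math.nan) for k, v in sorted(frac.items())],
        columns=["selection_call", "clustered_fraction"],
    )
    gio.write_results_tables(
        {
            "pairwise_metrics": pair_df,
            "families": fam_df,
            "pair_kaks": kaks_df,
            "clustered_fraction": frac_df,
        },
        res,
    )
    cl_df = pd.DataFrame(
        [(c.cluster_id, c.chrom, ";".join(c.members)) for c in clusters],
        columns=["cluster_id", "chrom", "members"],
    )
    gio.write_results_tables({"clusters": cl_df}, res)


def stage_coding(workdir: str | Path) -> None:
    """Variant effects, functional statuses, pseudogenes, presence/absence."""
    workdir = Path(workdir)
    inp = _inputs(workdir)
    res = _results(workdir)
    genes = [g for g in _load_genes(workdir) if g.species == "sorghum"]
    panels = _load_panels(workdir)
    regions = gio.read_fasta(inp / "regions.fasta")
    depth = gio.read_depth_bins(inp / "depth.tsv")
    groups = next(iter(panels.values())).groups
    effect_rows = []
    status_rows = []
    freq_rows = []
    pseudo_rows = []
    presence_rows = []
    pv_rows = []
    allele_kaks_rows = []
    for gene in genes:
        panel = panels.get(gene.chrom)
        if panel is None:
            continue
        win = panel.window(gene.start, gene.end)
        region = regions[gene.gene_id]
        effects = []
        for j in range(win.n_sites):
            if not gene.in_frame:
                break
            eff = ce.annotate_variant_effect(
                gene, int(win.positions[j]), win.ref[j], win.alt[j], region
            )
            effects.append(eff)
            effect_rows.append(
                (gene.gene_id, eff.position, eff.ref, eff.alt, eff.effect, int(eff.large_effect))
            )
        loss = ce.gene_loss_from_depth(depth, gene)
        deleted = {s: frac for s, (lost, frac) in loss.items()}
        statuses = ce.functional_statuses(gene, panel, effects, deleted)
        for st in statuses:
            status_rows.append(
                (st.gene_id, st.sample, int(st.functional), ";".join(st.reasons), st.deleted_fraction)
            )
        freqs = ce.nonfunctional_frequency(statuses, groups)
        freq_rows.append((gene.gene_id, *[freqs[g] for g in INGROUPS], freqs["overall"]))
        pseudo = ce.call_pseudogene(statuses)
        pseudo_rows.append((gene.gene_id, "" if pseudo is None else int(pseudo)))
        presence = {s: deleted.get(s, 0.0) <= 0.5 for s in panel.samples}
        presence_rows.append((gene.gene_id, ce.presence_absence_profile(presence, groups)))
        if gene.is_nbs and gene.in_frame:
            pv_rows.append(
                (
                    gene.gene_id,
                    ce.count_protein_variants(gene, panel, region, groups=INGROUPS),
                )
            )
            rec = _allele_kaks(gene, win, region, effects)
            if rec is not None:
                allele_kaks_rows.append((gene.gene_id, rec.ka, rec.ks, rec.ratio))
    gio.write_results_tables(
        {
            "effects": pd.DataFrame(
                effect_rows,
                columns=["gene_id", "position", "ref", "alt", "effect", "large_effect"],
            ),
            "functional_status": pd.DataFrame(
                status_rows,
                columns=["gene_id", "sample", "functional", "reasons", "deleted_fraction"],
            ),
            "nonfunctional_frequency": pd.DataFrame(
                freq_rows, columns=["gene_id", *INGROUPS, "overall"]
            ),
            "pseudogenes": pd.DataFrame(pseudo_rows, columns=["gene_id", "pseudogene"]),
            "presence_absence": pd.DataFrame(presence_rows, columns=["gene_id", "label"]),
            "protein_variants": pd.DataFrame(pv_rows, columns=["gene_id", "n_protein_variants"]),
            "allele_kaks": pd.DataFrame(
                allele_kaks_rows, columns=["gene_id", "ka", "ks", "ratio"]
            ),
        },
        res,
    )


def _allele_kaks(gene, win, region, effects):
    """Ka/Ks between the reference CDS and the most distant sample haplotype.

    Only synonymous/nonsynonymous substitutions are applied: large-effect
    alleles are the subject of the functional-status analysis instead.
    """
    from .genome_io import extract_cds, revcomp

    benign = {
        e.position: e for e in effects if e.effect in ("synonymous", "nonsynonymous")
    }
    sites = [j for j in range(win.n_sites) if int(win.positions[j]) in benign]
    if not sites:
        return None
    gpos = gene.cds_genomic_positions()
    index_of = {int(p): i for i, p in enumerate(gpos)}
    cds_ref = extract_cds(gene, region, gene.start)
    best = None
    for i in range(win.n_samples):
        carried = [j for j in sites if win.calls[i, j] == 1]
        if best is None or len(carried) > len(best):
            best = carried
    if not best:
        return None
    hap = list(cds_ref)
    for j in best:
        ci = index_of[int(win.positions[j])]
        alt = win.alt[j]
        hap[ci] = alt if gene.strand == "+" else revcomp(alt)
    try:
        return ce.ng86_kaks(cds_ref, "".join(hap), (gene.gene_id, "max_hap"))
    except InputError:
        return None


def stage_qtl(workdir: str | Path) -> None:
    """Project QTL, co-locate genes, QDR fraction, enrichment."""
    workdir = Path(workdir)
    inp = _inputs(workdir)
    res = _results(workdir)
    genes = [g for g in _load_genes(workdir) if g.species == "sorghum"]
    clens = _load_chrom_lengths(workdir)
    markers = qtl.read_markers(str(inp / "markers.tsv"))
    qtls = qtl.read_qtl_table(str(inp / "qtl.tsv"))
    projected = qtl.project_qtl(qtls, markers, clens)
    gio.write_bed(
        RegionSet("projected_qtl", [(q.chrom, q.bp_start, q.bp_end) for q in projected]),
        res / "projected_qtl.bed",
    )
    coloc = qtl.colocate(genes, projected)
    coloc_df = pd.DataFrame(
        [(g, ";".join(h), len(h)) for g, h in sorted(coloc.items())],
        columns=["gene_id", "qtl_ids", "n_qtl"],
    )
    qdr = qtl.qdr_fraction(projected, clens)
    background = {g.gene_id: bool(coloc[g.gene_id]) for g in genes}
    nbs_set = {g.gene_id for g in genes if g.is_nbs}
    chi2, p = qtl.qtl_enrichment(nbs_set, background)
    enr_df = pd.DataFrame(
        [
            ("nbs_in_qtl", chi2, p),
        ],
        columns=["test", "chi2", "p_value"],
    )
    qdr_df = pd.DataFrame(sorted(qdr.items()), columns=["measure", "value"])
    gio.write_results_tables(
        {"colocation": coloc_df, "qtl_enrichment": enr_df, "qdr": qdr_df}, res
    )


def stage_report(workdir: str | Path) -> dict:
    """Aggregate the headline numbers into report.json."""
    workdir = Path(workdir)
    res = _results(workdir)
    inp = _inputs(workdir)
    report: dict = {"version": __version__}
    cfg = json.loads((inp / "config.json").read_text())
    report["seed"] = cfg["seed"]
    report["config_hash"] = hashlib.sha256(
        (inp / "config.json").read_bytes()
    ).hexdigest()[:16]
    calls = pd.read_csv(res / "selection_calls.tsv", sep="\t")
    report["selection_calls"] = calls["call"].value_counts().to_dict()
    report["invariance"] = calls["invariance"].value_counts().to_dict()
    truth_path = inp / "truth_labels.tsv"
    if truth_path.exists():
        truth = pd.read_csv(truth_path, sep="\t")
        merged = calls.merge(truth, on="gene_id")
        report["confusion"] = {
            f"{t}->{c}": int(n)
            for (t, c), n in merged.groupby(["selection_class", "call"]).size().items()
        }
    # Figure-2 style: NBS enrichment in diversity tails per group
    gs = pd.read_csv(res / "gene_stats_gene_span.tsv", sep="\t")
    classes = pd.read_csv(inp / "classes.tsv", sep="\t")
    nbs_ids = set(classes.loc[classes["nbs_class"] != "non_nbs", "gene_id"])
    tail_enrichment = {}
    for grp, sub in gs.groupby("group"):
        vals = dict(zip(sub["gene_id"], sub["theta_pi"]))
        for side in ("upper", "lower"):
            tail = ps.empirical_tail(vals, ps.TailSpec("theta_pi", side, 0.05))
            universe = {g for g, v in vals.items() if np.isfinite(v)}
            inside = {g for g in universe if g in nbs_ids}
            chi2, p = ps.chi_square_enrichment(
                len(tail & inside), len(inside - tail),
                len(tail - inside), len(universe - inside - tail),
            )
            tail_enrichment[f"{grp}_{side}5"] = {"chi2": chi2, "p": p}
    report["nbs_tail_enrichment"] = tail_enrichment
    hka_path = res / "hka_results.tsv"
    if hka_path.exists():
        hka = pd.read_csv(hka_path, sep="\t")
        report["hka"] = hka.to_dict(orient="records")
    # Table-3 style Ka:Ks by selection call
    ak_path = res / "allele_kaks.tsv"
    if ak_path.exists():
        ak = pd.read_csv(ak_path, sep="\t").merge(calls[["gene_id", "call"]], on="gene_id")
        by_call = ak.dropna(subset=["ratio"]).groupby("call")["ratio"].mean()
        report["mean_allele_kaks_by_call"] = {k: float(v) for k, v in by_call.items()}
    fams = pd.read_csv(res / "families.tsv", sep="\t")
    report["families"] = {
        "n_clades": int(fams["clade_id"].nunique()),
        "n_multi_gene": int((fams["family_size"] >= 2).sum()),
        "ancestry": fams.drop_duplicates("clade_id")["ancestry"].value_counts().to_dict(),
    }
    frac = pd.read_csv(res / "clustered_fraction.tsv", sep="\t")
    report["clustered_fraction"] = dict(
        zip(frac["selection_call"], frac["clustered_fraction"])
    )
    qdr = pd.read_csv(res / "qdr.tsv", sep="\t")
    report["qdr"] = dict(zip(qdr["measure"], qdr["value"]))
    enr = pd.read_csv(res / "qtl_enrichment.tsv", sep="\t")
    report["qtl_enrichment"] = enr.to_dict(orient="records")
    nf = pd.read_csv(res / "nonfunctional_frequency.tsv", sep="\t")
    nonzero = nf.loc[nf["overall"] > 0, "overall"]
    report["nonfunctional_range"] = (
        [float(nonzero.min()), float(nonzero.max())] if len(nonzero) else [0.0, 0.0]
    )
    pseudo = pd.read_csv(res / "pseudogenes.tsv", sep="\t")
    report["n_pseudogenes"] = int(
        pd.to_numeric(pseudo["pseudogene"], errors="coerce").fillna(0).sum()
    )
    pa = pd.read_csv(res / "presence_absence.tsv", sep="\t")
    report["presence_absence"] = pa["label"].value_counts().to_dict()
    (res / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


def run_pipeline(
    config: synth.SimulationConfig, workdir: str | Path, strict_het: bool = False
) -> dict:
    """simulate -> stats -> scan -> families -> coding -> qtl -> report."""
    stage_simulate(config, workdir)
    stage_stats(workdir, strict_het)
    stage_scan(workdir)
    stage_families(workdir)
    stage_coding(workdir)
    stage_qtl(workdir)
    return stage_report(workdir)
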