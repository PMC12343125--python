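"""Two-arm comparison of posterior tree distributions (resolved vs semi-resolved).

The "resolved" arm stands for an analysis of the morphology-bearing taxa
alone; the "semi-resolved" arm stands for an analysis that additionally
anchors occurrence-only taxa through genus-level constraints, which in the
synthetic setting is emulated by a congruence-weighted pseudo-posterior over
the full taxon set. Both arms are brought onto the identical (morphology)
leafset and equal sample sizes before any metric is computed, then compared
on stratigraphic congruence, treespace spread, consensus/rogue/information
analytics, and highest-posterior-density (HPD) widths of node ages.

"Origin age" here is operationalized as the root age of each sampled tree
(no FBD origin parameter is inferred in this pipeline).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from . import consensus as cns
from . import simulate as sim
from . import treespace as tsp
from .congruence import congruence_over_sample
from .occurrences import TaxonAgeTable, one_occurrence_per_species
from .trees import TreeSample, prune_to_leafset, read_trees, subsample_trees

__all__ = [
    "HPDInterval",
    "ComparisonReport",
    "hpd_interval",
    "node_age_hpds",
    "compare_metric_distributions",
    "run_comparison",
    "default_synthetic_config",
    "report_schema",
]


# ---------------------------------------------------------------------------
# HPD intervals
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HPDInterval:
    lower: float
    upper: float
    mass: float = 0.95

    @property
    def width(self) -> float:
        return self.upper - self.lower


def hpd_interval(samples, mass: float = 0.95) -> HPDInterval:
    """Shortest contiguous window containing ceil(mass * n) order statistics.

    Ties between equally short windows are broken toward the earliest window.
    """
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 samples for an HPD interval")
    if not (0.0 < mass < 1.0):
        raise ValueError("mass must lie in (0, 1)")
    m = int(math.ceil(mass * n))
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return HPDInterval(lower=float(x[i]), upper=float(x[i + m - 1]), mass=mass)


def node_age_hpds(sample: TreeSample, reference, mass: float = 0.95) -> pd.DataFrame:
    """HPD width of each reference-tree clade's age across the sample.

    For every internal clade of ``reference`` (an MCC or other summary
    DatedTree on the sample's leafset) the clade's age is collected from each
    sample tree containing that clade; clades present in fewer than 2 trees
    are reported with a missing width.
    """
    from .splits import taxon_index

    index = taxon_index(sample.taxa)
    full = (1 << len(index)) - 1

    def clade_ages(dt):
        out = {}
        for nd in dt.tree.postorder_node_iter():
            if nd.is_leaf():
                nd._mask = 1 << index[nd.taxon.label]
            else:
                nd._mask = 0
                for c in nd.child_nodes():
                    nd._mask |= c._mask
                out.setdefault(nd._mask, nd.age)
        return out

    ref_ages = clade_ages(reference)
    rev = {i: lab for lab, i in index.items()}
    per_tree = [clade_ages(dt) for dt in sample]
    rows = []
    for mask in sorted(ref_ages, key=lambda m: (-m.bit_count(), m)):
        if mask.bit_count() < 2:
            continue
        ages = [ca[mask] for ca in per_tree if mask in ca]
        row = {"clade": ";".join(sorted(rev[i] for i in range(len(index))
                                        if mask >> i & 1)),
               "clade_size": mask.bit_count(),
               "is_root": mask == full,
               "n_containing": len(ages)}
        if len(ages) >= 2:
            h = hpd_interval(ages, mass)
            row.update(lower=h.lower, upper=h.upper, width=h.width)
        else:
            row.update(lower=math.nan, upper=math.nan, width=math.nan)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# between-arm tests
# ---------------------------------------------------------------------------

def compare_metric_distributions(x, y):
    """Two-sided Mann-Whitney U between two metric distributions."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) < 5 or len(y) < 5:
        raise ValueError("each sample needs at least 5 values")
    res = mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# report schema
# ---------------------------------------------------------------------------

class MetricTest(BaseModel):
    statistic: float
    p_raw: float
    p_holm: float
    test: str = "mann-whitney-u-two-sided"


class SpreadStats(BaseModel):
    sum_of_variances: float
    sum_of_ranges: float
    mean_centroid_distance: float


class ConsensusStats(BaseModel):
    n_nodes: int
    n_rogues: int
    information_content: float
    mean_improvement_from_rogue_removal: float
    sum_of_posterior_probabilities_mcc: float
    information_mode: str


class HPDModel(BaseModel):
    lower: float
    upper: float
    width: float
    mass: float


class ArmSummary(BaseModel):
    n_trees: int
    mig_mean: float
    mig_sd: float
    ger_mean: float
    sci_mean: float


class ComparisonReport(BaseModel):
    seed: int
    taxa: list[str]
    arms: dict[str, ArmSummary]
    tests: dict[str, MetricTest]
    treespace_metric: str
    eigenvalues: list[float]
    spread: dict[str, SpreadStats]
    consensus: dict[str, ConsensusStats]
    origin_hpd: dict[str, HPDModel]
    origin_percent_narrowing: float
    node_hpd_max_width: dict[str, float]
    node_hpd_percent_narrowing: float


def report_schema() -> dict:
    return ComparisonReport.model_json_schema()


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

def default_synthetic_config() -> dict:
    """Study conditions for the synthetic two-arm comparison.

    An entirely extinct clade (rho = 0) over a 20-Myr window with moderate
    net diversification and fossil recovery, a biased morphology subset
    (abundance exponent beta), stage-binned ages with occasional imprecise
    records, and pseudo-posteriors in which only the semi-resolved arm is
    congruence-weighted.
    """
    return {
        "synthetic": {
            "fbd": {"lambda_": 0.5, "mu": 0.3, "psi": 0.25, "t_origin": 20.0,
                    "rho": 0.0, "condition": "min_samples", "min_samples": 30},
            "tau_genus": 8.0,
            "n_stages": 10,
            "p_coarse": 0.15,
            "n_morph": 20,
            "beta": 1.5,
            "pseudo": {"n_trees": 250, "nni_rate": 2.0, "age_jitter_sd": 0.05,
                       "gamma_resolved": 0.0, "gamma_semi": 5.0},
        },
        "subsample": {"count": 120},
        "treespace_metric": "cid",
        "information_mode": "plain",
        "hpd_mass": 0.95,
        "figures": False,
    }


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _seeds(seed: int, n: int) -> list:
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n, dtype=np.uint32)]


def _build_arms_synthetic(config: dict, seeds: list):
    syn = config["synthetic"]
    fbd = sim.FBDParams(seed=seeds[0], **syn["fbd"])
    history, recon, occ = sim.simulate_fbd(fbd)
    genus_map = sim.assign_genera(history, syn["tau_genus"])
    occ["genus"] = occ["taxon"].map(genus_map)
    scale = sim.Timescale.uniform(fbd.t_origin, syn["n_stages"])
    binned = sim.bin_occurrence_ages(occ, scale, p_coarse=syn["p_coarse"],
                                     seed=seeds[1])
    ages = one_occurrence_per_species(binned, seed=seeds[2])
    extant = {t: (0.0, 0.0) for t in recon.taxa if t not in ages.taxa}
    ages = ages.merged_with(TaxonAgeTable(extant))
    morph = sim.select_morph_taxa(occ, k=syn["n_morph"], beta=syn["beta"],
                                  seed=seeds[3])
    ps = syn["pseudo"]
    semi_full = sim.generate_pseudo_posterior(
        recon.tree, n_trees=ps["n_trees"], nni_rate=ps["nni_rate"],
        age_jitter_sd=ps["age_jitter_sd"],
        congruence_weight=ps["gamma_semi"], ages=ages, seed=seeds[4])
    semi = TreeSample([prune_to_leafset(dt, morph) for dt in semi_full],
                      provenance={"arm": "semi-resolved"})
    res_truth = prune_to_leafset(recon.tree, morph)
    resolved = sim.generate_pseudo_posterior(
        res_truth, n_trees=ps["n_trees"], nni_rate=ps["nni_rate"],
        age_jitter_sd=ps["age_jitter_sd"],
        congruence_weight=ps["gamma_resolved"],
        ages=ages.subset(morph) if ps["gamma_resolved"] > 0 else None,
        seed=seeds[5])
    return {"resolved": resolved, "semi-resolved": semi}, ages.subset(morph)


def _build_arms_files(config: dict):
    burnin = config.get("burnin", 0.1)
    fmt = config.get("format", "newick")
    resolved = read_trees(config["resolved_trees"], format=fmt, burnin=burnin)
    semi = read_trees(config["semi_resolved_trees"], format=fmt, burnin=burnin)
    ages = TaxonAgeTable.from_csv(config["ages_csv"])
    morph = config["morph_taxa"]
    if isinstance(morph, str):
        morph = [l.strip() for l in open(morph) if l.strip()]
    morph = sorted(morph)
    if frozenset(morph) != resolved.taxa:
        raise ValueError("resolved arm leafset must equal the morphology taxon set")
    semi = TreeSample([prune_to_leafset(dt, morph) for dt in semi],
                      provenance={"arm": "semi-resolved"})
    return {"resolved": resolved, "semi-resolved": semi}, ages.subset(morph)


def run_comparison(config: dict, seed: int, out_dir=None) -> dict:
    """Run the full two-arm comparison; returns the report as a plain dict.

    The report is validated against :class:`ComparisonReport` and, when
    ``out_dir`` is given, serialized (with per-arm congruence tables and,
    optionally, figures) under that directory. Identical (config, seed)
    yields byte-identical report JSON.
    """
    seeds = _seeds(seed, 10)
    if "synthetic" in config:
        arms, ages = _build_arms_synthetic(config, seeds)
    else:
        arms, ages = _build_arms_files(config)

    # equal-size subsample of both arms on the identical leafset
    assert arms["resolved"].taxa == arms["semi-resolved"].taxa
    sub = config.get("subsample", {})
    sizes = []
    for name, s in arms.items():
        if "fraction" in sub:
            sizes.append(int(round(len(s) * sub["fraction"])))
        else:
            sizes.append(min(sub.get("count", len(s)), len(s)))
    n_keep = min(sizes)
    arms = {name: subsample_trees(s, count=n_keep, seed=seeds[6 + i])
            for i, (name, s) in enumerate(sorted(arms.items()))}

    # stratigraphic congruence per arm
    cong = {name: congruence_over_sample(s, ages) for name, s in arms.items()}
    arm_summaries = {
        name: ArmSummary(
            n_trees=len(arms[name]),
            mig_mean=float(df["MIG"].mean()),
            mig_sd=float(df["MIG"].std(ddof=0)),
            ger_mean=float(df["GER"].mean(skipna=True)),
            sci_mean=float(df["SCI"].mean()),
        ) for name, df in cong.items()}

    # between-arm tests with Holm adjustment
    raw = {}
    for metric in ("MIG", "GER", "SCI"):
        stat, p = compare_metric_distributions(cong["resolved"][metric],
                                               cong["semi-resolved"][metric])
        raw[metric] = (stat, p)
    _, p_holm, _, _ = multipletests([raw[m][1] for m in ("MIG", "GER", "SCI")],
                                    method="holm")
    tests = {m: MetricTest(statistic=raw[m][0], p_raw=raw[m][1],
                           p_holm=float(ph))
             for m, ph in zip(("MIG", "GER", "SCI"), p_holm)}

    # joint treespace
    metric = config.get("treespace_metric", "cid")
    names = sorted(arms)
    joint = TreeSample([dt for name in names for dt in arms[name]],
                       provenance={"arms": names})
    groups = [name for name in names for _ in arms[name]]
    values = np.concatenate([cong[name]["MIG"].to_numpy() for name in names])
    D = tsp.distance_matrix(joint, metric=metric)
    emb = tsp.pcoa_embed(D, metric=metric, groups=groups, values=values)
    surface = tsp.landscape(emb)
    dens = tsp.density_map(emb)
    spread = {g: SpreadStats(**st) for g, st in tsp.spread_stats(emb).items()}

    # consensus / rogue / MCC analytics per arm
    info_mode = config.get("information_mode", "plain")
    rogue_mode = config.get("rogue_mode", "support_weighted")
    consensus_stats = {}
    mcc_refs = {}
    for name in names:
        s = arms[name]
        maj = cns.majority_rule_consensus(s)
        info = cns.consensus_information(maj, mode=info_mode)
        rogue = cns.detect_rogues(s, mode=rogue_mode)
        mcc, sum_pp = cns.mcc_tree(s)
        mcc_refs[name] = mcc
        consensus_stats[name] = ConsensusStats(
            n_nodes=maj.node_count,
            n_rogues=len(rogue.rogues),
            information_content=info,
            mean_improvement_from_rogue_removal=rogue.mean_improvement,
            sum_of_posterior_probabilities_mcc=sum_pp,
            information_mode=info_mode)

    # HPD widths: origin (root age) and per-clade node ages
    mass = config.get("hpd_mass", 0.95)
    origin_hpd = {}
    node_max = {}
    node_tables = {}
    for name in names:
        s = arms[name]
        h = hpd_interval([dt.root_age for dt in s], mass)
        origin_hpd[name] = HPDModel(lower=h.lower, upper=h.upper,
                                    width=h.width, mass=mass)
        tab = node_age_hpds(s, mcc_refs[name], mass)
        node_tables[name] = tab
        inner = tab[~tab["is_root"]]["width"].dropna()
        node_max[name] = float(inner.max()) if len(inner) else 0.0

    def narrowing(w_res, w_semi):
        return 0.0 if w_res == 0 else 100.0 * (1.0 - w_semi / w_res)

    report = ComparisonReport(
        seed=seed,
        taxa=sorted(arms["resolved"].taxa),
        arms=arm_summaries,
        tests=tests,
        treespace_metric=metric,
        eigenvalues=[float(v) for v in emb.eigenvalues[:10]],
        spread=spread,
        consensus=consensus_stats,
        origin_hpd=origin_hpd,
        origin_percent_narrowing=narrowing(origin_hpd["resolved"].width,
                                           origin_hpd["semi-resolved"].width),
        node_hpd_max_width=node_max,
        node_hpd_percent_narrowing=narrowing(node_max["resolved"],
                                             node_max["semi-resolved"]),
    )
    out = report.model_dump()
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "report.json", "w") as fh:
            json.dump(out, fh, indent=2, sort_keys=True)
        with open(out_dir / "report.schema.json", "w") as fh:
            json.dump(report_schema(), fh, indent=2, sort_keys=True)
        for name in names:
            cong[name].to_csv(out_dir / f"congruence_{name}.tsv",
                              sep="\t", index=False)
            node_tables[name].to_csv(out_dir / f"node_hpd_{name}.tsv",
                                     sep="\t", index=False)
        if config.get("figures", False):
            _figures(out_dir, cong, emb, surface, dens, origin_hpd, node_tables)
    return out


# ---------------------------------------------------------------------------
# figures
# ---------------------------------------------------------------------------

def _figures(out_dir, cong, emb, surface, dens, origin_hpd, node_tables):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    names = sorted(cong)
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2))
    for ax, metric in zip(axes, ("MIG", "GER", "SCI")):
        data = [cong[n][metric].dropna() for n in names]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(names) + 1), names, rotation=20)
        ax.set_title(metric)
    fig.tight_layout()
    fig.savefig(out_dir / "congruence_metrics.png", dpi=150)
    plt.close(fig)

    xy = emb.axes2()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.contourf(surface.grid_x, surface.grid_y, surface.grid_z,
                levels=15, cmap="viridis", alpha=0.6)
    markers = {n: m for n, m in zip(names, "os^v")}
    for n in names:
        sel = [i for i, g in enumerate(emb.groups) if g == n]
        sc = ax.scatter(xy[sel, 0], xy[sel, 1], c=emb.values[sel],
                        marker=markers[n], s=18, cmap="viridis",
                        edgecolors="k", linewidths=0.2, label=n)
    fig.colorbar(sc, ax=ax, label="MIG (myr)")
    ax.legend()
    ax.set_xlabel("PCo 1")
    ax.set_ylabel("PCo 2")
    fig.tight_layout()
    fig.savefig(out_dir / "treespace_landscape.png", dpi=150)
    plt.close(fig)

    fig, axes = plt.subplots(1, len(dens), figsize=(4.5 * len(dens), 3.6))
    if len(dens) == 1:
        axes = [axes]
    for ax, (g, (gx, gy, Z)) in zip(axes, sorted(dens.items())):
        ax.pcolormesh(gx, gy, Z, cmap="inferno", shading="auto")
        ax.set_title(g)
    fig.tight_layout()
    fig.savefig(out_dir / "treespace_density.png", dpi=150)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 2.5))
    for i, n in enumerate(names):
        h = origin_hpd[n]
        ax.plot([h.lower, h.upper], [i, i], lw=3)
        ax.plot([(h.lower + h.upper) / 2], [i], "o", color="k")
    ax.set_yticks(range(len(names)), names)
    ax.set_xlabel("origin (root) age, Ma")
    fig.tight_layout()
    fig.savefig(out_dir / "origin_hpd.png", dpi=150)
    plt.close(fig)
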