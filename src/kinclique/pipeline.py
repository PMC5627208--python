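"""End-to-end orchestration: simulate or load data, run every stage,
write a deterministic JSON report plus CSV/GraphML/Newick artefacts."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import affiliation, community, dominance, ethogram, hpmt, kinship
from . import synthetic
from .genotypes import read_genepop
from .matrices import write_matrix_csv

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "validate_inputs", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds and knobs in one place.

    Paper-unstated constants (CPM k, w*, half-life, DAI mode) are
    stand-ins surfaced here so they can be varied from the YAML config.
    """

    # inputs: either a directory with the CSV/GenePop bundle, or a
    # synthetic scenario seed
    input_dir: str | None = None
    scenario_seed: int | None = 0
    out_dir: str = "kinclique_out"

    hwi_edge_threshold: float = 0.17
    dai_edge_threshold: float = 0.19
    cpm_k: int = 3                 # stand-in: smallest clique size
    cpm_w_star: float = 1.0        # stand-in: percolation weight threshold
    half_life_days: float = 14.0   # stand-in: affiliation memory half-life
    dai_mode: str = "initiator_share"
    n_perm: int = 999
    seed: int = 0
    n_scans: int = 3213
    n_groom_bouts: int = 3047
    n_agonistic: int = 2194

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        for name in ("hwi_edge_threshold", "dai_edge_threshold",
                     "cpm_w_star", "half_life_days"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cpm_k < 3:
            raise ValueError("cpm_k must be >= 3")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.input_dir is None and self.scenario_seed is None:
            raise ValueError("either input_dir or scenario_seed is required")


def _load_bundle(indir: Path) -> dict:
    bundle = {}
    for name in ("scans", "grooming", "agonistic", "gps_amb", "gps_bb"):
        path = indir / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(path)
        bundle[name] = pd.read_csv(path)
    bundle["genotypes"] = read_genepop(indir / "genotypes.gen")
    truth_path = indir / "truth.json"
    if truth_path.exists():
        with open(truth_path) as fh:
            bundle["truth"] = json.load(fh)
    return bundle


def validate_inputs(config: PipelineConfig) -> dict:
    """Structural validation: files, ID consistency, duplicates, ranges.

    Returns a report dict with ``errors`` and ``warnings`` lists; a
    behavioural individual missing from the genotype panel is an error,
    a scan day outside the GPS day range only a warning.
    """
    config.validate()
    errors: list[str] = []
    warnings_: list[str] = []
    if config.input_dir is None:
        return {"errors": [], "warnings": [], "source": "synthetic"}
    indir = Path(config.input_dir)
    try:
        bundle = _load_bundle(indir)
    except FileNotFoundError as e:
        return {"errors": [f"missing file: {e}"], "warnings": [],
                "source": str(indir)}
    genotyped = set(bundle["genotypes"].individuals)
    for table, cols in (("scans", ("id_a", "id_b")),
                        ("grooming", ("initiator", "recipient")),
                        ("agonistic", ("actor", "recipient"))):
        frame = bundle[table]
        for col in cols:
            for line_no, val in frame[col].items():
                if str(val) not in genotyped:
                    errors.append(
                        f"{table}.csv line {line_no + 2}: id {val!r} "
                        "not genotyped")
                    break  # one diagnostic per column is enough
        if frame.duplicated().any():
            warnings_.append(f"{table}.csv: duplicate records")
    gps_days = set(bundle["gps_amb"]["day"]) & set(bundle["gps_bb"]["day"])
    scan_days = set(bundle["scans"].get("day", pd.Series(dtype=int)))
    outside = scan_days - gps_days
    if outside:
        warnings_.append(
            f"{len(outside)} scan day(s) outside GPS coverage")
    return {"errors": errors, "warnings": warnings_, "source": str(indir)}


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.ndarray,)):
        return o.tolist()
    if isinstance(o, pd.Series):
        return {str(k): v for k, v in o.items()}
    raise TypeError(f"not JSON-serialisable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run affiliation -> dominance -> kinship -> community -> HPMT ->
    ethogram stats and write the report bundle.

    Identical config + seed gives a byte-identical report.
    """
    config.validate()
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    if config.input_dir is not None:
        bundle = _load_bundle(Path(config.input_dir))
        truth = bundle.get("truth")
        ages = None
        if truth:
            ages = pd.Series({i["id"]: i["age_years"]
                              for i in truth["individuals"]})
    else:
        scenario = synthetic.make_scenario(seed=int(config.scenario_seed))
        bundle = synthetic.simulate_all(
            scenario, n_scans=config.n_scans,
            n_groom_bouts=config.n_groom_bouts,
            n_agonistic=config.n_agonistic)
        synthetic.write_scenario_bundle(scenario, bundle, outdir / "inputs")
        ages = scenario.ages
        truth = None

    report: dict = {"config": asdict(config)}

    # --- affiliation -------------------------------------------------------
    hwi = affiliation.compute_hwi(bundle["scans"])
    dai, g_counts = affiliation.compute_dai(bundle["grooming"],
                                            mode=config.dai_mode)
    partition = affiliation.cluster_subgroups(hwi)
    cent = affiliation.eigenvector_centrality(hwi)
    report["affiliation"] = {
        "n_individuals": hwi.shape[0],
        "n_subgroups": partition.n_groups,
        "cliquishness": partition.cliquishness,
        "subgroups": partition.groups(),
        "mean_hwi_within": None,
        "mean_hwi_between": None,
    }
    w, b = affiliation.group_mean_contrast(hwi, partition.assignment)
    report["affiliation"]["mean_hwi_within"] = w
    report["affiliation"]["mean_hwi_between"] = b

    # --- dominance ---------------------------------------------------------
    wins, conflict_report = dominance.build_conflict_matrix(bundle["agonistic"])
    dom = dominance.david_scores(wins)
    steep = dominance.hierarchy_steepness(
        wins, n_perm=min(config.n_perm, 1000),
        seed=int(rng.integers(2**31 - 1)))
    lin = dominance.hierarchy_linearity(
        wins, n_perm=min(config.n_perm, 1000),
        seed=int(rng.integers(2**31 - 1)))
    report["dominance"] = {
        "bouts": conflict_report,
        "steepness": steep.steepness, "steepness_r2": steep.r2,
        "steepness_p": steep.p,
        "linearity_h_corrected": lin.h_corrected, "linearity_p": lin.p,
        "rank_order": dom.rank_order,
    }

    # --- kinship -----------------------------------------------------------
    em = kinship.estimate_allele_freqs_em(bundle["genotypes"])
    rel = kinship.lr_relatedness(bundle["genotypes"], em,
                                 null_correction=True)
    tree = kinship.upgma_relatedness(rel)
    div = kinship.diversity_stats(bundle["genotypes"])
    hwe = {loc: asdict(kinship.hwe_chisq(bundle["genotypes"], loc))
           for loc in bundle["genotypes"].loci}
    holm = ethogram.sequential_bonferroni(
        [hwe[loc]["p"] for loc in bundle["genotypes"].loci
         if not hwe[loc]["no_test"]])
    w_r, b_r = affiliation.group_mean_contrast(rel, partition.assignment)
    perm = hpmt.label_permutation_test(
        rel, partition.assignment, n_perm=config.n_perm,
        seed=int(rng.integers(2**31 - 1)))
    report["kinship"] = {
        "null_freqs": {loc: em.null_freq(loc) for loc in em.freqs},
        "diversity_means": div.loc["mean"].to_dict(),
        "mean_relatedness_within": w_r,
        "mean_relatedness_between": b_r,
        "label_permutation_p": perm.p,
        "hwe_rejected_after_holm": int(sum(holm.reject)),
    }

    # --- HPMT: the headline attribution ------------------------------------
    ids = list(hwi.index)
    ages_s = ages.loc[ids] if ages is not None else pd.Series(
        np.arange(len(ids), dtype=float), index=ids)
    age_diff = pd.DataFrame(
        np.abs(ages_s.to_numpy()[:, None] - ages_s.to_numpy()[None, :]),
        index=ids, columns=ids)
    nds = dom.nds.reindex(ids)
    rank_diff = pd.DataFrame(
        np.abs(nds.to_numpy()[:, None] - nds.to_numpy()[None, :]),
        index=ids, columns=ids)
    factors = {"relatedness": rel, "age_diff": age_diff,
               "rank_diff": rank_diff}
    analysis = hpmt.hpmt_analysis(hwi, factors, n_perm=config.n_perm,
                                  seed=int(rng.integers(2**31 - 1)))
    report["hpmt_proximity"] = analysis.to_dict()
    dai_sym = (dai + dai.T) / 2.0
    analysis_groom = hpmt.hpmt_analysis(dai_sym, factors,
                                        n_perm=config.n_perm,
                                        seed=int(rng.integers(2**31 - 1)))
    report["hpmt_grooming"] = analysis_groom.to_dict()
    mant = hpmt.mantel(hwi, rel, n_perm=config.n_perm,
                       seed=int(rng.integers(2**31 - 1)))
    report["mantel_hwi_relatedness"] = {"r": mant.r, "p": mant.p}

    # --- community dynamics -------------------------------------------------
    days = sorted(set(bundle["scans"]["day"])) if "day" in bundle["scans"] else []
    if len(days) >= 2:
        weights = community.edge_weight_series(
            bundle["scans"], days=days,
            half_life_days=config.half_life_days)
        daily = {d: community.cpm_communities(weights[d], k=config.cpm_k,
                                              w_star=config.cpm_w_star)
                 for d in days}
        timeline = community.track_communities(daily)
        dist = community.band_distance(bundle["gps_amb"], bundle["gps_bb"])
        paired = sorted(set(timeline.sizes.index) & set(dist.index))
        comm_report = {
            "mean_community_size": float(timeline.sizes.mean()),
            "n_days": len(days),
        }
        if len(paired) >= 10:
            model = community.community_distance_model(
                timeline.sizes, dist)
            comm_report["distance_model"] = {
                "pearson_r": model.pearson_r, "spearman_r": model.spearman_r,
                "bin_means": {str(k): (None if pd.isna(v) else float(v))
                              for k, v in model.bin_means.items()},
            }
        report["community"] = comm_report
    else:
        report["community"] = {"skipped": "scan table has no day column"}

    # --- ethogram statistics ------------------------------------------------
    tally = ethogram.tally_ethogram(
        bundle["agonistic"], list(dominance.AGONISTIC_BEHAVIOURS))
    gof = ethogram.chisq_gof(list(tally.counts.values()))
    high = sum(tally.percents[b] for b in ("biting", "fighting", "chasing"))
    report["ethogram"] = {
        "counts": tally.counts, "percents": tally.percents,
        "chisq": gof.statistic, "chisq_df": gof.df, "chisq_p": gof.p,
        "high_intensity_share_pct": round(high, 2),
    }

    # --- artefacts ----------------------------------------------------------
    write_matrix_csv(hwi, outdir / "hwi.csv")
    write_matrix_csv(dai, outdir / "dai.csv")
    write_matrix_csv(rel, outdir / "relatedness.csv")
    wins.to_csv(outdir / "conflict_wins.csv")
    pd.DataFrame({"DS": dom.ds, "NDS": dom.nds}).assign(
        rank=lambda f: f["NDS"].rank(ascending=False, method="first")
    ).to_csv(outdir / "dominance.csv")
    with open(outdir / "relatedness_upgma.nwk", "w") as fh:
        fh.write(tree.to_newick() + "\n")
    node_attrs = pd.DataFrame({"nds": dom.nds.reindex(ids),
                               "centrality": cent.reindex(ids),
                               "subgroup": pd.Series(partition.assignment)})
    sociogram = affiliation.filter_sociogram(
        hwi, config.hwi_edge_threshold, node_attrs=node_attrs)
    nx.write_graphml(sociogram, outdir / "sociogram_hwi.graphml")
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True,
                  default=_json_default)
    return report
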