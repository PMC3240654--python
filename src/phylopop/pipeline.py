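"""End-to-end analysis runs: alignment in, report bundle out.

A run takes either a FASTA alignment plus an id→group TSV, or a
polymorphic-site haplotype table plus a locality→group TSV, and writes
the full set of reports: haplotype membership, site classification,
diagnostic sites, the K2P distance matrix and group summaries, an NJ
tree with bootstrap supports, an optional molecular-clock dating, and a
one-stop summary TSV at the printed precisions (percent to one decimal,
diversity to three).  Machine-readable outputs keep full precision.
Identical config and seed reproduce every output byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import __version__
from .clock import calibrate, date_divergence
from .distances import distance_matrix, group_mean
from .haplotypes import (
    classify_sites,
    collapse_haplotypes,
    diagnostic_sites,
    haplotype_diversity,
)
from .io import (
    Alignment,
    InputError,
    expand_table,
    parse_haplotype_table,
    read_fasta,
    read_group_map,
    write_tsv,
)
from .njtree import bootstrap_support, root_at, write_newick


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Configuration for :func:`run_all`.

    Exactly one of ``fasta`` (with ``groups`` mapping sequence ids) or
    ``table`` (with ``groups`` mapping localities) must be given.
    """

    outdir: str
    fasta: str | None = None
    table: str | None = None
    groups: str | None = None
    bootstrap: int = 1000
    seed: int = 0
    tolerance: int = 2
    filler: str = "A"
    percent: bool = True
    root: str | None = None
    d_cal: float | None = None
    T_cal: float | None = None
    d_obs: float | None = None
    per_lineage: bool = False

    _FLOAT_KEYS = ("d_cal", "T_cal", "d_obs")
    _INT_KEYS = ("bootstrap", "seed", "tolerance")
    _BOOL_KEYS = ("percent", "per_lineage")

    def __post_init__(self) -> None:
        if (self.fasta is None) == (self.table is None):
            raise ConfigError("exactly one of 'fasta' or 'table' must be set")
        if self.groups is None:
            raise ConfigError("missing required field 'groups' (group-map TSV)")
        if self.bootstrap < 1:
            raise ConfigError("bootstrap must be >= 1")
        if self.tolerance < 0:
            raise ConfigError("tolerance must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        """Parse a flat ``key: value`` config file; kwargs override."""
        values: dict[str, Any] = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.strip()
                if not line or line.startswith("#"):
                    continue
                if ":" not in line:
                    raise ConfigError(f"{path}:{lineno}: expected 'key: value'")
                key, value = (part.strip() for part in line.split(":", 1))
                if key in cls._INT_KEYS:
                    values[key] = int(value)
                elif key in cls._FLOAT_KEYS:
                    values[key] = float(value)
                elif key in cls._BOOL_KEYS:
                    values[key] = value.lower() in ("1", "true", "yes")
                else:
                    values[key] = value
        values.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**values)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def load_alignment(config: RunConfig) -> Alignment:
    groups = read_group_map(config.groups)
    if config.table is not None:
        table = parse_haplotype_table(config.table)
        return expand_table(table, groups, filler=config.filler)
    alignment = read_fasta(config.fasta)
    return alignment.with_groups(groups)


def _fmt_pct(d: float, percent: bool) -> str:
    return f"{100.0 * d:.1f}" if percent else f"{d:.6f}"


def run_all(config: RunConfig) -> dict[str, Any]:
    """Run every stage and write the report bundle into ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"phylopop {__version__}",
        f"seed: {config.seed}",
        f"bootstrap replicates: {config.bootstrap}",
        f"nearly-fixed tolerance: {config.tolerance}",
        f"invariant-column filler: {config.filler}",
    ]

    def stage(name: str):
        log.append(f"stage: {name}")

    try:
        stage("load")
        alignment = load_alignment(config)
        labels = alignment.group_labels()
        if len(labels) != 2:
            raise InputError(f"expected exactly 2 groups, found {labels}")
        ga, gb = labels

        stage("haplotypes")
        haps = collapse_haplotypes(alignment)
        hap_rows = []
        for k, hap in enumerate(haps, 1):
            hap_rows.append(
                {"haplotype": k, "count": hap.count, "members": ",".join(hap.member_ids)}
            )
        write_tsv(pd.DataFrame(hap_rows).set_index("haplotype"), outdir / "haplotypes.tsv")
        diversity = haplotype_diversity([h.count for h in haps])
        by_group = {}
        for g in labels:
            sub = alignment.subset(alignment.group_indices(g))
            by_group[g] = collapse_haplotypes(sub)

        stage("sites")
        sites = classify_sites(alignment)
        site_rows = [
            {
                "column": j + 1,
                "class": "variable" if sites.variable[j] else "invariant",
                "indel": bool(sites.contains_gap[j]),
                "parsimony_informative": bool(sites.parsimony_informative[j]),
            }
            for j in range(sites.length)
            if sites.variable[j]
        ]
        write_tsv(pd.DataFrame(site_rows).set_index("column"), outdir / "sites.tsv")

        stage("diagnostic")
        diag = diagnostic_sites(alignment, ga, gb, tolerance=config.tolerance)
        diag_rows = [
            {
                "column": col,
                "class": "fixed" if col in diag.fixed else "nearly_fixed",
                "states": ";".join(
                    f"{g}:" + ",".join(f"{s}x{c}" for s, c in states.items())
                    for g, states in diag.states_by_group[col].items()
                ),
            }
            for col in sorted(diag.fixed + diag.nearly_fixed)
        ]
        write_tsv(pd.DataFrame(diag_rows, columns=["column", "class", "states"]).set_index("column"),
                  outdir / "diagnostic.tsv")

        stage("distances")
        matrix = distance_matrix(alignment)
        write_tsv(matrix.to_dataframe(), outdir / "distance_matrix.tsv")
        summaries = {
            "between": group_mean(
                alignment, "between", groups=(ga, gb), matrix=matrix,
                bootstrap=config.bootstrap, seed=config.seed,
            ),
            f"within_{ga}": group_mean(
                alignment, "within", group=ga, matrix=matrix,
                bootstrap=config.bootstrap, seed=config.seed + 1,
            ),
            f"within_{gb}": group_mean(
                alignment, "within", group=gb, matrix=matrix,
                bootstrap=config.bootstrap, seed=config.seed + 2,
            ),
        }
        dist_rows = [
            {
                "comparison": name,
                "mode": s.mode,
                "n_pairs": s.n_pairs,
                "mean_d": f"{s.mean_d:.8f}",
                "se_d": f"{s.se_d:.8f}",
                "replicates": s.replicates,
            }
            for name, s in summaries.items()
        ]
        write_tsv(pd.DataFrame(dist_rows).set_index("comparison"),
                  outdir / "group_distances.tsv")

        stage("njtree")
        tree, redrawn = bootstrap_support(
            alignment, B=config.bootstrap, seed=config.seed
        )
        if redrawn:
            log.append(f"bootstrap replicates redrawn (undefined distances): {redrawn}")
        ep_split = frozenset(
            alignment.ids[i] for i in alignment.group_indices(ga)
        )
        monophyletic = tree.is_monophyletic(ep_split)
        split_support = None
        all_leaves = frozenset(alignment.ids)
        canonical = ep_split if min(all_leaves) not in ep_split else all_leaves - ep_split
        node = tree.bipartitions().get(canonical)
        if node is not None:
            split_support = node.support
        out_tree = tree if config.root is None else root_at(tree, config.root)
        write_newick(out_tree, outdir / "tree.nwk")

        stage("clock")
        clock_result = None
        if config.d_cal is not None and config.T_cal is not None:
            cal = calibrate(config.d_cal, config.T_cal, per_lineage=config.per_lineage)
            d_obs = config.d_obs
            se_obs = None
            if d_obs is None:
                # observed distance in the calibration's units (% if percent)
                d_obs = summaries["between"].mean_d * (100.0 if config.percent else 1.0)
                se_obs = summaries["between"].se_d * (100.0 if config.percent else 1.0)
            clock_result = date_divergence(d_obs, cal, se_d=se_obs)
            clock_df = pd.DataFrame(
                [{
                    "d_cal": cal.d_cal,
                    "T_cal": cal.T_cal,
                    "rate": cal.rate,
                    "per_lineage": cal.per_lineage,
                    "d_obs": clock_result.d_obs,
                    "T": clock_result.T,
                    "T_low": clock_result.T_low,
                    "T_high": clock_result.T_high,
                }]
            )
            write_tsv(clock_df.set_index("d_cal"), outdir / "clock.tsv")

        stage("summary")
        pct = config.percent
        summary_rows = [
            ("n_individuals", alignment.n),
            ("alignment_length", alignment.length),
            ("n_haplotypes", len(haps)),
            (f"n_haplotypes_{ga}", len(by_group[ga])),
            (f"n_haplotypes_{gb}", len(by_group[gb])),
            ("haplotype_diversity", f"{diversity.h:.3f}"),
            ("variable_sites", sites.n_variable),
            ("indel_sites", sites.n_indel),
            ("parsimony_informative_sites", sites.n_parsimony_informative),
            ("fixed_differences", len(diag.fixed)),
            ("nearly_fixed_differences", len(diag.nearly_fixed)),
            (f"mean_K2P_between_{'pct' if pct else 'sub_per_site'}",
             _fmt_pct(summaries["between"].mean_d, pct)),
            (f"mean_K2P_within_{ga}_{'pct' if pct else 'sub_per_site'}",
             _fmt_pct(summaries[f"within_{ga}"].mean_d, pct)),
            (f"mean_K2P_within_{gb}_{'pct' if pct else 'sub_per_site'}",
             _fmt_pct(summaries[f"within_{gb}"].mean_d, pct)),
            (f"monophyly_{ga}", monophyletic),
            ("split_bootstrap_support", "" if split_support is None else f"{split_support:.1f}"),
        ]
        if clock_result is not None:
            summary_rows += [
                ("clock_rate_per_MY", f"{calibrate(config.d_cal, config.T_cal, config.per_lineage).rate:.4g}"),
                ("divergence_time_MY", f"{clock_result.T:.2f}"),
            ]
        summary = pd.DataFrame(summary_rows, columns=["quantity", "value"])
        summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)

        (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    except Exception as exc:
        failed = log[-1].removeprefix("stage: ") if log and log[-1].startswith("stage:") else "?"
        raise type(exc)(f"[stage {failed}] {exc}") from exc

    return {
        "alignment": alignment,
        "haplotypes": haps,
        "haplotypes_by_group": by_group,
        "diversity": diversity,
        "sites": sites,
        "diagnostic": diag,
        "matrix": matrix,
        "summaries": summaries,
        "tree": tree,
        "monophyly": monophyletic,
        "split_support": split_support,
        "clock": clock_result,
        "summary_table": summary,
    }
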