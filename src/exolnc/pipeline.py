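"""End-to-end orchestration: expression selection -> Venn intersection
-> motif enrichment -> seed mapping -> expression crosslink -> RBP scan
-> length diagnostics, with one TSV report per stage and a manifest.

Every stage is a thin call into the library modules, so each can be
re-run independently; a stage failure aborts the run with the stage
name in the exception.  Reports are deterministic functions of the
inputs recorded (with checksums) in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .expression import (
    ExpressionTable,
    SelectionConfig,
    intersect_enriched,
    select_enriched,
    select_outlier_mirnas,
)
from .motifs import FilterTrace, MotifConfig, enrich_from_sets, count_kmers
from .rbp import DEFAULT_THRESHOLD, compare_rbp_counts, read_pwms, scan_set
from .seeds import crosslink_expression, map_motifs, read_mirna_fasta
from .seqdata import Compartment, read_fasta
from .stats import anova_lengths, kendall_tau_b

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and thresholds for a full run."""

    test_fasta: Path
    control_fasta: Path
    mirna_fasta: Path
    out_dir: Path
    expression_tsv: Path | None = None  # lncRNA fold changes
    mirna_expression_tsv: Path | None = None
    pwm_file: Path | None = None
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    allow_wobble: bool = True
    rbp_threshold: float = DEFAULT_THRESHOLD

    def __post_init__(self) -> None:
        for name in ("test_fasta", "control_fasta", "mirna_fasta"):
            p = getattr(self, name)
            setattr(self, name, Path(p))
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        for name in ("expression_tsv", "mirna_expression_tsv", "pwm_file"):
            p = getattr(self, name)
            if p is not None:
                setattr(self, name, Path(p))
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name}: {p}")
        self.out_dir = Path(self.out_dir)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_full(cfg: RunConfig) -> dict:
    """Execute every stage; returns the manifest dict (also written as
    ``manifest.json`` next to the per-stage TSV reports)."""
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "inputs": {},
        "config": {
            "fc_min": cfg.selection.fc_min,
            "z_cut_expression": cfg.selection.z_cut,
            "k": cfg.motif.k,
            "z_cut_motifs": cfg.motif.z_cut,
            "allow_wobble": cfg.allow_wobble,
            "rbp_threshold": cfg.rbp_threshold,
        },
        "stages": {},
        "reports": [],
    }
    for name in (
        "test_fasta",
        "control_fasta",
        "mirna_fasta",
        "expression_tsv",
        "mirna_expression_tsv",
        "pwm_file",
    ):
        p = getattr(cfg, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(p)}

    def report(name: str, frame: pd.DataFrame) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=False)
        manifest["reports"].append(name)

    # stage 1: expression selection + Venn
    if cfg.expression_tsv is not None:
        try:
            table = ExpressionTable.from_file(cfg.expression_tsv)
            direction = "down" if (table.frame.to_numpy() < 0).all() else "up"
            per_line = {
                line: select_enriched(table, line, cfg.selection, direction=direction)
                for line in table.cell_lines
            }
            common, regions = intersect_enriched(per_line)
            report(
                "selection.tsv",
                pd.DataFrame(
                    {
                        "cell_line": list(per_line),
                        "n_selected": [len(s) for s in per_line.values()],
                    }
                ),
            )
            report(
                "venn.tsv",
                pd.DataFrame(
                    {
                        "region": ["&".join(k) for k in regions],
                        "size": list(regions.values()),
                    }
                ),
            )
            manifest["stages"]["selection"] = {
                "direction": direction,
                "n_common": len(common),
                "common": sorted(common),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("selection", exc) from exc

    # stage 2: motif enrichment
    try:
        test_set = read_fasta(cfg.test_fasta, label="test", compartment=Compartment.EXOSOME)
        control_set = read_fasta(
            cfg.control_fasta, label="control", compartment=Compartment.CELL
        )
        trace = FilterTrace()
        enriched = enrich_from_sets(test_set, control_set, cfg.motif, trace=trace)
        report(
            "enriched_motifs.tsv",
            pd.DataFrame(
                [
                    (m.motif, m.count_test, m.count_control, m.diff, m.z)
                    for m in enriched
                ],
                columns=["motif", "count_test", "count_control", "diff", "z"],
            ),
        )
        manifest["stages"]["motif_enrichment"] = trace.__dict__
    except Exception as exc:  # noqa: BLE001
        raise StageError("motif_enrichment", exc) from exc

    # stage 3: seed mapping
    try:
        mirnas = read_mirna_fasta(cfg.mirna_fasta)
        seed_report = map_motifs(enriched, mirnas, allow_wobble=cfg.allow_wobble)
        rows = [
            (motif, sm.mirna_id, sm.wobble_count)
            for motif, sms in seed_report.matches.items()
            for sm in sms
        ]
        report(
            "seed_matches.tsv",
            pd.DataFrame(rows, columns=["motif", "mirna", "wobbles"]),
        )
        manifest["stages"]["seed_match"] = {
            "n_motifs_in": len(enriched),
            "n_with_seed": len(seed_report.matches),
            "n_no_seed": len(seed_report.no_seed_motifs),
            "no_seed_motifs": seed_report.no_seed_motifs,
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("seed_match", exc) from exc

    # stage 4: crosslink with over-expressed miRNAs
    if cfg.mirna_expression_tsv is not None:
        try:
            mtab = ExpressionTable.from_file(cfg.mirna_expression_tsv, kind="miRNA")
            over: dict[str, float] = {}
            for line in mtab.cell_lines:
                for mid in select_outlier_mirnas(mtab, line):
                    fc = float(mtab.frame.loc[mid, line])
                    over[mid] = max(over.get(mid, fc), fc)
            rows = crosslink_expression(seed_report, over)
            report(
                "crosslink.tsv",
                pd.DataFrame(
                    [
                        (r.motif, r.mirna_id or "NA-expression", r.fold_change)
                        for r in rows
                    ],
                    columns=["motif", "mirna", "fold_change"],
                ),
            )
            manifest["stages"]["crosslink"] = {
                "n_overexpressed_mirnas": len(over),
                "n_motifs_with_overexpressed_match": len(
                    {r.motif for r in rows if r.mirna_id is not None}
                ),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("crosslink", exc) from exc

    # stage 5: RBP scan and comparison
    if cfg.pwm_file is not None:
        try:
            pwms = read_pwms(cfg.pwm_file)
            _, counts_test = scan_set(test_set, pwms, cfg.rbp_threshold)
            _, counts_control = scan_set(control_set, pwms, cfg.rbp_threshold)
            comparisons = compare_rbp_counts(
                counts_test, counts_control, len(test_set), len(control_set)
            )
            report(
                "rbp_comparison.tsv",
                pd.DataFrame(
                    [
                        (
                            c.rbp_name,
                            c.count_test,
                            c.count_control,
                            round(c.rate_test, 4),
                            round(c.rate_control, 4),
                            round(c.rate_ratio, 4),
                            c.p_value,
                        )
                        for c in comparisons
                    ],
                    columns=[
                        "rbp",
                        "sites_test",
                        "sites_control",
                        "rate_test",
                        "rate_control",
                        "rate_ratio",
                        "p_value",
                    ],
                ),
            )
            manifest["stages"]["rbp_scan"] = {
                "n_pwms": len(pwms),
                "sites_test": int(sum(counts_test.values())),
                "sites_control": int(sum(counts_control.values())),
            }
        except Exception as exc:  # noqa: BLE001
            raise StageError("rbp_scan", exc) from exc

    # stage 6: length diagnostics
    try:
        diag_rows = []
        if enriched:
            motif_set = [m.motif for m in enriched]
            for tset in (test_set, control_set):
                lengths, freqs = [], []
                for rec in tset:
                    counts = count_kmers([rec.sequence], cfg.motif.k)
                    lengths.append(rec.length)
                    freqs.append(sum(counts.get(m, 0) for m in motif_set))
                if len(set(lengths)) > 1 and len(set(freqs)) > 1:
                    res = kendall_tau_b(lengths, freqs)
                    diag_rows.append(
                        (tset.label, res.n, round(res.coefficient, 4), res.strength)
                    )
        report(
            "length_correlation.tsv",
            pd.DataFrame(
                diag_rows,
                columns=["population", "n", "tau_b", "strength"],
            ),
        )
        aov = anova_lengths(test_set.lengths(), control_set.lengths())
        manifest["stages"]["lengths"] = {
            "anova_F": aov.f_statistic,
            "anova_p": aov.p_value,
            "mean_length_test": aov.group_means[0],
            "mean_length_control": aov.group_means[1],
        }
    except Exception as exc:  # noqa: BLE001
        raise StageError("lengths", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
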