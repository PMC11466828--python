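"""Study orchestration: validate inputs, run the triad analysis, cohort
statistics and bead-panel workups, and write a self-describing report bundle.

Every output carries a provenance header (mask version, serology version,
seed, scope) so a run can be reproduced from its artifacts. Validation
errors are collected per file and reported together before aborting.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cohort import compare_cohorts, summarize_cohort
from .datasets import load_packaged_store
from .mismatch import analyze_triad, triad_table, write_reports_json
from .sab import analyze_panel, read_panels_csv
from .store import AlleleStore, build_store, load_alignment, load_mask, \
    load_serology
from .subjects import read_typings_csv

log = logging.getLogger("hlarepeat")


@dataclass
class RunConfig:
    typings: str
    alleledb: str | None = None       # directory of *_prot.txt alignments
    mask: str | None = None
    serology: str | None = None
    panels: str | None = None
    cohorts: dict[str, list[str]] = field(default_factory=dict)
    exclude: list[str] = field(default_factory=list)
    class2_scope: str = "interlocus"
    threshold: float = 1000.0
    out_dir: str = "hlarepeat-out"
    seed: int | None = None

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> list[str]:
        errors = []
        for name in ("typings", "alleledb", "mask", "serology", "panels"):
            value = getattr(self, name)
            if value is not None and not Path(value).exists():
                errors.append(f"{name}: path {value} does not exist")
        if self.threshold <= 0:
            errors.append("threshold must be > 0")
        if self.class2_scope not in ("interlocus", "intralocus"):
            errors.append(f"unknown class2_scope {self.class2_scope!r}")
        return errors


def load_store_from_config(config: RunConfig) -> AlleleStore:
    if config.alleledb is None:
        return load_packaged_store()
    alignments = []
    for path in sorted(Path(config.alleledb).glob("*_prot.txt")):
        locus = path.name.split("_")[0].upper()
        alignments.append(load_alignment(path, locus=locus))
    if config.mask is None or config.serology is None:
        raise ValueError("alleledb requires explicit mask and serology files")
    return build_store(alignments, load_mask(config.mask),
                       load_serology(config.serology))


def _provenance(store: AlleleStore, config: RunConfig) -> dict:
    return {
        "mask_version": store.mask.version,
        "serology_version": store.serology.version,
        "class2_scope": config.class2_scope,
        "threshold": config.threshold,
        "seed": config.seed,
    }


def _header(prov: dict, columns_doc: str) -> str:
    lines = [f"# {k}: {v}" for k, v in sorted(prov.items())]
    lines.append(f"# columns: {columns_doc}")
    return "\n".join(lines) + "\n"


def run_study(config: RunConfig) -> dict:
    """Run the full workflow and write the report bundle to ``out_dir``.

    Outputs: ``triads.tsv`` (mismatch count table), ``reports.json`` (full
    mismatch sets), ``cohorts.tsv`` + ``comparison.json`` when two cohorts
    are configured, and ``dsa_calls.json`` when bead panels are given.
    Returns the bundle as in-memory objects.
    """
    errors = config.validate()
    if errors:
        raise ValueError("invalid configuration:\n" + "\n".join(errors))

    store = load_store_from_config(config)
    prov = _provenance(store, config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log.info("reading typings from %s", config.typings)
    triads = read_typings_csv(config.typings)
    reports = [analyze_triad(t, store, scope=config.class2_scope)
               for t in triads]
    table = triad_table(reports)

    tsv = out / "triads.tsv"
    with open(tsv, "w") as fh:
        fh.write(_header(prov, "patient_id, comparison (kidney/msc/repeated), "
                               "split counts A B C DR DQ, amino-acid counts "
                               "per locus group"))
        table.to_csv(fh, sep="\t", index=False)
    write_reports_json(reports, out / "reports.json", provenance=prov)

    bundle: dict = {"reports": reports, "table": table, "provenance": prov}

    if config.cohorts:
        by_id = {r.patient_id: r for r in reports}
        summaries = {}
        for cid, patients in config.cohorts.items():
            members = [by_id[p] for p in patients if p in by_id]
            summaries[cid] = summarize_cohort(members, cohort_id=cid,
                                              exclude=config.exclude)
        rows = []
        for cid, s in summaries.items():
            row = {"cohort": cid, "n": s.n_analyzed}
            for g, m in s.medians.items():
                row[f"median_{g}"] = m
            rows.append(row)
        with open(out / "cohorts.tsv", "w") as fh:
            fh.write(_header(prov, "cohort, n analyzed, median repeated "
                                   "amino-acid mismatches per locus group"))
            pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)
        bundle["summaries"] = summaries
        if len(summaries) == 2:
            s1, s2 = summaries.values()
            test = compare_cohorts(s1, s2)
            (out / "comparison.json").write_text(json.dumps(
                {"provenance": prov, "u": test.u, "z": test.z,
                 "p_asymptotic": test.p_asymptotic, "p_exact": test.p_exact,
                 "p_exact_mid": test.p_exact_mid,
                 "median_a": test.median_a, "median_b": test.median_b},
                indent=2, sort_keys=True) + "\n")
            bundle["comparison"] = test

    if config.panels:
        panels = read_panels_csv(config.panels, threshold=config.threshold)
        by_id = {t.patient_id: t for t in triads}
        calls = []
        for panel in panels:
            pid = panel.sample_id.split(":")[0]
            if pid not in by_id:
                raise ValueError(f"panel {panel.sample_id}: no triad for "
                                 f"patient {pid}")
            t = by_id[pid]
            calls.append(analyze_panel(panel, t.recipient, t.kidney, t.msc,
                                       store, scope=config.class2_scope))
        (out / "dsa_calls.json").write_text(json.dumps(
            {"provenance": prov, "calls": [c.to_dict() for c in calls]},
            indent=2, sort_keys=True) + "\n")
        bundle["calls"] = calls

    return bundle
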