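"""Config-driven end-to-end run: digest -> annotate -> screen -> report.

The configuration is a plain mapping (usually parsed from YAML by the CLI):

.. code-block:: yaml

    fasta: substrate.fasta          # required
    treatments:                     # one or more named enzyme treatments
      papain:        {stage1: [papain]}
      papain_prep:   {stage1: [papain], stage2: [prep]}
    reference_table: null           # TSV; null -> packaged fixture
    known_table: null               # TSV; null -> packaged fixture
    scorer: baseline                # "baseline" | path to score TSV | null
    threshold: 0.0
    allergen: pass                  # "pass" | verdict TSV path
    toxin: pass                     # "pass" | verdict TSV path
    out_dir: out

Every referenced file is validated before any work starts; on failure the
run raises :class:`ConfigError` and removes whatever partial outputs were
written, so a directory either holds a complete, reproducible result set or
nothing.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import activity as _activity
from .digest import (
    degree_of_hydrolysis,
    digest,
    merge_unique,
    release_frequency_AE,
    relative_frequency_W,
    sequential_digest,
)
from .cascade import constant_pass, load_predicate, run_cascade
from .enzymes import get_enzyme, load_registry
from .io import read_fasta, write_peptide_table


class ConfigError(ValueError):
    pass


def _resolve_enzymes(names, where):
    if not names:
        raise ConfigError(f"{where}: at least one enzyme required")
    try:
        return [get_enzyme(n) for n in names]
    except KeyError as exc:
        raise ConfigError(str(exc))


def _validate(config: dict) -> dict:
    cfg = dict(config)
    if "fasta" not in cfg:
        raise ConfigError("config is missing 'fasta'")
    if not Path(cfg["fasta"]).exists():
        raise ConfigError(f"fasta file not found: {cfg['fasta']}")
    treatments = cfg.get("treatments") or {}
    if not treatments:
        raise ConfigError("config needs at least one treatment")
    for label, spec in treatments.items():
        _resolve_enzymes(spec.get("stage1"), f"treatment {label!r} stage1")
        if spec.get("stage2"):
            _resolve_enzymes(spec["stage2"], f"treatment {label!r} stage2")
    for key in ("reference_table", "known_table"):
        path = cfg.get(key)
        if path and not Path(path).exists():
            raise ConfigError(f"{key} not found: {path}")
    for key in ("allergen", "toxin"):
        value = cfg.get(key, "pass")
        if value != "pass" and not Path(value).exists():
            raise ConfigError(f"{key} predicate file not found: {value}")
    scorer = cfg.get("scorer", "baseline")
    if scorer not in (None, "baseline") and not Path(scorer).exists():
        raise ConfigError(f"scorer file not found: {scorer}")
    threshold = cfg.get("threshold", _activity.ACTIVITY_THRESHOLD)
    if not -10.0 <= float(threshold) <= 10.0:
        raise ConfigError(f"activity threshold {threshold} outside documented range")
    return cfg


def run_config(config: dict, out_dir=None) -> dict:
    """Execute a validated config; returns a summary dict.

    Writes per-treatment peptide tables, release statistics, the cascade
    report, and a log of the rule/reference table versions used.
    """
    cfg = _validate(config)
    out = Path(out_dir or cfg.get("out_dir", "."))
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run(cfg, out, written)
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise


def _run(cfg: dict, out: Path, written: list) -> dict:
    protein = read_fasta(cfg["fasta"])[0]
    reference = _activity.load_reference_table(cfg.get("reference_table"))
    known = _activity.load_known_aht(cfg.get("known_table"))
    scorer_cfg = cfg.get("scorer", "baseline")
    if scorer_cfg is None:
        scorer = None
    elif scorer_cfg == "baseline":
        scorer = _activity.baseline_scorer
    else:
        scorer = _activity.FileBackedScorer(scorer_cfg)
    threshold = float(cfg.get("threshold", _activity.ACTIVITY_THRESHOLD))

    stats = {}
    all_active = []
    ref_seqs = set(reference)
    for label, spec in cfg["treatments"].items():
        stage1 = _resolve_enzymes(spec.get("stage1"), label)
        if spec.get("stage2"):
            stage2 = _resolve_enzymes(spec["stage2"], label)
            result = sequential_digest(protein, stage1, stage2, treatment=label)
        else:
            result = digest(protein, stage1, treatment=label)
        annotated = _activity.annotate_peptides(
            result.peptides, reference, scorer, threshold
        )
        table_path = out / f"peptides_{label}.tsv"
        write_peptide_table(annotated, table_path)
        written.append(table_path)
        stats[label] = {
            "dh_percent": degree_of_hydrolysis(result),
            "release_frequency_AE": release_frequency_AE(
                result.peptides, ref_seqs, len(protein.sequence)
            ),
            "n_peptides": len(result.peptides),
            "n_active": sum(1 for p in annotated if p.annotations.get("active")),
        }
        try:
            stats[label]["relative_frequency_W"] = relative_frequency_W(
                result.peptides, ref_seqs, protein
            )
        except ValueError:
            stats[label]["relative_frequency_W"] = None
        all_active.append([p for p in annotated if p.annotations.get("active")])

    merged = merge_unique(all_active)
    merged_path = out / "peptides_merged_active.tsv"
    write_peptide_table(merged, merged_path)
    written.append(merged_path)

    allergen_cfg = cfg.get("allergen", "pass")
    toxin_cfg = cfg.get("toxin", "pass")
    allergen = (
        constant_pass("allergen")
        if allergen_cfg == "pass"
        else load_predicate(allergen_cfg, kind="allergen")
    )
    toxin = (
        constant_pass("toxin")
        if toxin_cfg == "pass"
        else load_predicate(toxin_cfg, kind="toxin")
    )
    report = run_cascade(merged, allergen, toxin, known_reference=known)
    report_path = out / "cascade_report.json"
    report.to_json(report_path)
    written.append(report_path)

    stats_path = out / "stats.json"
    stats_path.write_text(json.dumps(stats, indent=2, sort_keys=True) + "\n")
    written.append(stats_path)

    registry = load_registry()
    log_path = out / "run_log.txt"
    lines = [f"substrate: {protein.id} ({len(protein.sequence)} residues)"]
    for name in sorted(registry):
        e = registry[name]
        lines.append(f"enzyme {name} (EC {e.ec_number}): {e.source}")
    lines.append(f"activity threshold: {threshold}")
    log_path.write_text("\n".join(lines) + "\n")
    written.append(log_path)

    return {
        "stats": stats,
        "n_merged_active": len(merged),
        "report": report.to_dict(),
        "outputs": [str(p) for p in written],
    }
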