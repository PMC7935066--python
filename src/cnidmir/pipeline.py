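"""End-to-end orchestration: curate -> find-targets -> degradome-verify -> conserve.

A :class:`PipelineConfig` (TOML-serializable) names the inputs and the
rule/threshold/cleavage parameters; :func:`run_pipeline` executes the
stages in order, writes every stage's table before the next starts, and
drops a machine-readable manifest (package version, config hash, seed)
next to the results. Re-running with the same config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import tomllib
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__, io as cio
from .conservation import (
    annotate_site_region,
    candidate_homolog_sites,
    classify_conservation,
    reciprocal_best_hits,
    reciprocal_map,
    site_location_conserved,
)
from .curation import CurationThresholds, blacklist_filter, evaluate_candidate
from .degradome import CleavageRule, map_degradome, verify_sites
from .targets import TargetRuleSet, scan_transcript, validate_site

logger = logging.getLogger("cnidmir")


class PipelineError(RuntimeError):
    """A stage failure carrying the stage name and offending record."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r}: {message}")
        self.stage = stage


@dataclass
class SpeciesInputs:
    name: str
    precursors_fasta: str
    precursor_table: str
    read_stacks: str
    transcripts_fasta: str
    cds_table: str | None = None
    structures: str | None = None


@dataclass
class PipelineConfig:
    reference: SpeciesInputs
    other: SpeciesInputs
    degradome_fasta: str
    out_dir: str
    blacklists: dict[str, str] = field(default_factory=dict)
    rules: TargetRuleSet = field(default_factory=TargetRuleSet)
    thresholds: CurationThresholds = field(default_factory=CurationThresholds)
    cleavage: CleavageRule = field(default_factory=CleavageRule)
    rng_seed: int = 0
    n_shuffles: int = 99
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    @classmethod
    def from_toml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as handle:
            data = tomllib.load(handle)
        return cls(
            reference=SpeciesInputs(**data["reference"]),
            other=SpeciesInputs(**data["other"]),
            degradome_fasta=data["degradome_fasta"],
            out_dir=data["out_dir"],
            blacklists=data.get("blacklists", {}),
            rules=TargetRuleSet(**data.get("rules", {})),
            thresholds=CurationThresholds(**data.get("thresholds", {})),
            cleavage=CleavageRule(**data.get("cleavage", {})),
            rng_seed=int(data.get("rng_seed", 0)),
            n_shuffles=int(data.get("n_shuffles", 99)),
            log_level=data.get("log_level", "INFO"),
        )

    def to_toml(self, path: str | Path) -> None:
        lines = [
            f"degradome_fasta = {json.dumps(self.degradome_fasta)}",
            f"out_dir = {json.dumps(self.out_dir)}",
            f"rng_seed = {self.rng_seed}",
            f"n_shuffles = {self.n_shuffles}",
            f"log_level = {json.dumps(self.log_level)}",
        ]
        for section, obj in (("reference", self.reference), ("other", self.other)):
            lines.append(f"\n[{section}]")
            for k, v in dataclasses.asdict(obj).items():
                if v is not None:
                    lines.append(f"{k} = {json.dumps(v)}")
        if self.blacklists:
            lines.append("\n[blacklists]")
            lines.extend(f"{k} = {json.dumps(v)}" for k, v in self.blacklists.items())
        for section, obj in (
            ("rules", self.rules), ("thresholds", self.thresholds), ("cleavage", self.cleavage),
        ):
            lines.append(f"\n[{section}]")
            for k, v in dataclasses.asdict(obj).items():
                lines.append(f"{k} = {json.dumps(v)}")
        Path(path).write_text("\n".join(lines) + "\n")


def _audit_frame(evaluations) -> pd.DataFrame:
    rows = [
        {
            "candidate_id": e.candidate_id,
            "score_pass": int(e.score_pass),
            "overhang_pass": int(e.overhang_pass),
            "five_prime_pass": int(e.five_prime_pass),
            "complementarity_pass": int(e.complementarity_pass),
            "reads_pass": int(e.reads_pass),
            "fold_pvalue_pass": int(e.fold_pvalue_pass),
            "overhang": "" if e.measured_overhang is None else e.measured_overhang,
            "five_prime": round(e.measured_five_prime, 4),
            "pairs": e.measured_pairs,
            "reads": e.measured_reads,
            "pvalue": round(e.measured_pvalue, 6),
            "bona_fide": int(e.bona_fide),
            "failure_reasons": ",".join(e.failure_reasons),
        }
        for e in sorted(evaluations, key=lambda e: e.candidate_id)
    ]
    return pd.DataFrame(rows)


def _curate_species(sp: SpeciesInputs, config: PipelineConfig, out: Path) -> dict[str, str]:
    try:
        candidates = cio.load_precursors(
            sp.precursors_fasta, sp.precursor_table, species=sp.name, structures=sp.structures
        )
        stacks = cio.read_read_stacks(sp.read_stacks)
    except (OSError, ValueError) as exc:
        raise PipelineError("curate", f"{sp.name}: {exc}") from exc
    blacklists = {name: cio.read_fasta(path) for name, path in config.blacklists.items()}
    kept, removed = blacklist_filter(candidates, blacklists)
    if removed:
        pd.DataFrame(
            [{"candidate_id": c.id, "source": src} for c, src in removed]
        ).to_csv(out / f"{sp.name}.blacklisted.tsv", sep="\t", index=False)
    evaluations = []
    for cand in kept:
        if cand.id not in stacks:
            raise PipelineError("curate", f"{sp.name}: no read stack for candidate {cand.id}")
        evaluations.append(
            evaluate_candidate(
                cand, stacks[cand.id], config.thresholds,
                n_shuffles=config.n_shuffles, seed=config.rng_seed,
            )
        )
    _audit_frame(evaluations).to_csv(out / f"{sp.name}.curation.tsv", sep="\t", index=False)
    bona_fide = {
        c.id: c.mature_seq
        for c, e in zip(kept, evaluations)
        if e.bona_fide
    }
    cio.write_fasta(out / f"{sp.name}.bona_fide.fasta", bona_fide)
    logger.info("%s: %d/%d candidates bona fide", sp.name, len(bona_fide), len(candidates))
    return bona_fide


def _find_targets(matures: dict[str, str], transcripts: dict[str, str], config: PipelineConfig):
    sites = []
    for tid in sorted(transcripts):
        for mid in sorted(matures):
            for site in scan_transcript(
                matures[mid], transcripts[tid], config.rules, mirna_id=mid, transcript_id=tid
            ):
                sites.append(validate_site(matures[mid], site, transcripts[tid], config.rules))
    return sites


def analyze_scenario(scenario) -> dict:
    """In-memory pipeline over a :class:`~cnidmir.simulate.SpeciesScenario`.

    Scans both species' transcriptomes with their repertoires, verifies the
    reference sites against the scenario degradome, finds reciprocal
    orthologs, and classifies each verified reference pair. Returns the
    classification records plus the intermediate site/evidence lists.
    """
    sp_ref, sp_other = sorted(scenario.transcripts)
    tx_ref, tx_other = scenario.transcripts[sp_ref], scenario.transcripts[sp_other]
    sites = {}
    for sp, tx in ((sp_ref, tx_ref), (sp_other, tx_other)):
        found = []
        for tid in sorted(tx):
            for fam in sorted(scenario.repertoires[sp]):
                mat = scenario.repertoires[sp][fam]
                for s in scan_transcript(mat, tx[tid], scenario.rules, mirna_id=fam, transcript_id=tid):
                    found.append(validate_site(mat, s, tx[tid], scenario.rules))
        sites[sp] = found
    valid_ref = [s for s in sites[sp_ref] if s.validated]
    read_5p = map_degradome(scenario.degradome_reads[sp_ref], tx_ref)
    evidence = verify_sites(valid_ref, read_5p)
    verified = [e.site for e in evidence if e.verified]
    rbh = reciprocal_best_hits(tx_ref, tx_other)
    homolog_candidates = candidate_homolog_sites(
        verified, tx_ref, tx_other, rbh, scenario.repertoires[sp_ref], scenario.rules
    )
    other_all = sites[sp_other] + [c for c in homolog_candidates if not c.validated]
    reference_records = sorted({(s.mirna_id, s.transcript_id) for s in verified})
    records = classify_conservation(
        reference_records, rbh, other_all, set(scenario.repertoires[sp_other])
    )
    return {
        "sites": sites,
        "evidence": evidence,
        "verified": verified,
        "rbh": rbh,
        "records": records,
    }


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns a report bundle of the key tables."""
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # stage 1: curation
    matures_ref = _curate_species(config.reference, config, out)
    matures_other = _curate_species(config.other, config, out)
    if not matures_ref:
        warnings.warn("no bona fide miRNAs in the reference species; downstream reports empty", stacklevel=2)

    # stage 2: target discovery + duplex validation
    try:
        tx_ref = cio.read_fasta(config.reference.transcripts_fasta)
        tx_other = cio.read_fasta(config.other.transcripts_fasta)
    except (OSError, ValueError) as exc:
        raise PipelineError("find-targets", str(exc)) from exc
    sites_ref = _find_targets(matures_ref, tx_ref, config)
    sites_other = _find_targets(matures_other, tx_other, config)
    cio.write_sites_tsv(out / f"{config.reference.name}.sites.tsv", sites_ref)
    cio.write_sites_bed(out / f"{config.reference.name}.sites.bed", sites_ref)
    cio.write_sites_tsv(out / f"{config.other.name}.sites.tsv", sites_other)

    # stage 3: degradome verification of reference sites
    try:
        deg = cio.read_fasta(config.degradome_fasta)
    except (OSError, ValueError) as exc:
        raise PipelineError("degradome-verify", str(exc)) from exc
    read_5p = map_degradome(sorted(deg.items()), tx_ref)
    valid_ref = [s for s in sites_ref if s.validated]
    evidence = verify_sites(valid_ref, read_5p, config.cleavage)
    cio.write_evidence_tsv(out / f"{config.reference.name}.degradome.tsv", evidence)
    verified_sites = [e.site for e in evidence if e.verified]

    # stage 4: cross-species conservation
    rbh = reciprocal_best_hits(tx_ref, tx_other)
    pd.DataFrame(
        [dataclasses.asdict(p) for p in rbh]
    ).to_csv(out / "rbh.tsv", sep="\t", index=False)
    homolog_candidates = candidate_homolog_sites(
        verified_sites, tx_ref, tx_other, rbh, matures_ref, config.rules
    )
    other_all = [s for s in sites_other if s.validated is not None] + [
        c for c in homolog_candidates if not c.validated
    ]
    reference_records = sorted({(s.mirna_id, s.transcript_id) for s in verified_sites})
    records = classify_conservation(reference_records, rbh, other_all, set(matures_other))

    cds_ref = cio.read_cds_table(config.reference.cds_table) if config.reference.cds_table else {}
    cds_other = cio.read_cds_table(config.other.cds_table) if config.other.cds_table else {}
    site_by_ref = {(s.mirna_id, s.transcript_id): s for s in verified_sites}
    other_by_tx: dict[str, list] = {}
    for s in other_all:
        other_by_tx.setdefault(s.transcript_id, []).append(s)
    rows = []
    for rec in sorted(records, key=lambda r: (r.ref_target, r.ref_mirna)):
        ref_site = site_by_ref.get((rec.ref_mirna, rec.ref_target))
        if ref_site is not None:
            rec.ref_region = annotate_site_region(ref_site, cds_ref.get(rec.ref_target))
        if rec.homolog is not None and rec.category in ("I", "II", "III"):
            fam = rec.other_mirna if rec.category in ("I", "II") else rec.ref_mirna
            candidates = [s for s in other_by_tx.get(rec.homolog, []) if s.mirna_id == fam]
            if candidates and ref_site is not None:
                other_site = candidates[0]
                rec.other_region = annotate_site_region(other_site, cds_other.get(rec.homolog))
                rec.site_location_conserved = bool(
                    site_location_conserved(
                        ref_site, other_site, tx_ref[rec.ref_target], tx_other[rec.homolog],
                        cds_a=cds_ref.get(rec.ref_target), cds_b=cds_other.get(rec.homolog),
                    )
                )
        rows.append(
            {
                "ref_target": rec.ref_target,
                "ref_mirna": rec.ref_mirna,
                "homolog": rec.homolog or "",
                "other_mirna": rec.other_mirna or "",
                "category": rec.category,
                "ref_region": rec.ref_region,
                "other_region": rec.other_region,
                "site_location_conserved": (
                    "" if rec.site_location_conserved is None else int(rec.site_location_conserved)
                ),
                "reason": rec.reason,
            }
        )
    conservation_df = pd.DataFrame(
        rows,
        columns=[
            "ref_target", "ref_mirna", "homolog", "other_mirna", "category",
            "ref_region", "other_region", "site_location_conserved", "reason",
        ],
    )
    conservation_df.to_csv(out / "conservation.tsv", sep="\t", index=False)

    manifest = {
        "package": "cnidmir",
        "version": __version__,
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return {
        "bona_fide": {config.reference.name: matures_ref, config.other.name: matures_other},
        "sites": {config.reference.name: sites_ref, config.other.name: sites_other},
        "evidence": evidence,
        "rbh": rbh,
        "records": records,
        "conservation_table": conservation_df,
        "manifest": manifest,
    }
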