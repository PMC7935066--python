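"""File formats: FASTA, TSV tables, BED intervals, dot-bracket sidecars.

Human-facing TSV reports use 1-based inclusive coordinates; BED files and
everything in memory use 0-based half-open intervals.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import normalize_rna
from .curation import PrecursorCandidate, ReadStack
from .degradome import CleavageEvidence
from .targets import TargetSite


class FastaParseError(ValueError):
    pass


def read_fasta(path: str | Path, rna: bool = True) -> dict[str, str]:
    """Read FASTA into {id: sequence}; errors name the file and line."""
    path = Path(path)
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}:{lineno}: expected a '>' header, got {line.strip()[:30]!r}"
                    )
                break
    out: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if rna:
            try:
                seq = normalize_rna(seq)
            except ValueError as exc:
                raise FastaParseError(f"{path}: record {record.id}: {exc}") from exc
        if record.id in out:
            raise FastaParseError(f"{path}: duplicate record id {record.id!r}")
        out[record.id] = seq
    return out


def write_fasta(path: str | Path, seqs: dict[str, str]) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_precursor_table(path: str | Path) -> pd.DataFrame:
    """Precursor annotations: id, mature_start, mature_end, star_start,
    star_end (0-based half-open), optional score column."""
    df = pd.read_csv(path, sep="\t")
    required = {"id", "mature_start", "mature_end", "star_start", "star_end"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def load_precursors(
    fasta: str | Path, table: str | Path, species: str = "", structures: str | Path | None = None
) -> list[PrecursorCandidate]:
    seqs = read_fasta(fasta)
    df = read_precursor_table(table)
    struct = dict(read_structures(structures)) if structures else {}
    candidates = []
    for row in df.itertuples():
        if row.id not in seqs:
            raise ValueError(f"precursor {row.id!r} in {table} missing from {fasta}")
        score = float(row.score) if "score" in df.columns and pd.notna(row.score) else None
        candidates.append(
            PrecursorCandidate(
                id=row.id,
                precursor_seq=seqs[row.id],
                mature_interval=(int(row.mature_start), int(row.mature_end)),
                star_interval=(int(row.star_start), int(row.star_end)),
                structure=struct.get(row.id),
                upstream_score=score,
                species=species,
            )
        )
    return candidates


def write_precursor_table(path: str | Path, candidates: list[PrecursorCandidate]) -> None:
    rows = [
        {
            "id": c.id,
            "mature_start": c.mature_interval[0],
            "mature_end": c.mature_interval[1],
            "star_start": c.star_interval[0],
            "star_end": c.star_interval[1],
            "score": c.upstream_score if c.upstream_score is not None else "",
        }
        for c in candidates
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_structures(path: str | Path) -> dict[str, str]:
    """Dot-bracket sidecar: FASTA-like, '>id' then one structure line."""
    out: dict[str, str] = {}
    name = None
    with open(path) as handle:
        for line in handle:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
            elif name is not None:
                out[name] = line
                name = None
    return out


def read_read_stacks(path: str | Path) -> dict[str, ReadStack]:
    """Read stacks TSV: candidate_id, start, length, count."""
    df = pd.read_csv(path, sep="\t")
    stacks: dict[str, ReadStack] = {}
    for cid, group in df.groupby("candidate_id", sort=True):
        entries = [
            (int(r.start), int(r.length), int(r["count"]))
            for _, r in group.iterrows()
        ]
        stacks[str(cid)] = ReadStack(entries=sorted(entries))
    return stacks


def write_read_stacks(path: str | Path, stacks: dict[str, ReadStack]) -> None:
    rows = [
        {"candidate_id": cid, "start": s, "length": ln, "count": c}
        for cid, stack in sorted(stacks.items())
        for s, ln, c in stack.entries
    ]
    pd.DataFrame(rows, columns=["candidate_id", "start", "length", "count"]).to_csv(
        path, sep="\t", index=False
    )


def _site_sort_key(site: TargetSite):
    return (site.transcript_id, site.start, site.mirna_id)


def sites_to_frame(sites: list[TargetSite]) -> pd.DataFrame:
    """Site report with 1-based inclusive coordinates."""
    rows = [
        {
            "transcript": s.transcript_id,
            "start": s.start + 1,
            "end": s.end,
            "mirna_id": s.mirna_id,
            "seed_mm": s.seed_mismatches,
            "tail_mm": s.tail_mismatches,
            "pos1_mismatch": int(s.pos1_mismatch),
            "last_nt_unpaired": int(s.last_nt_unpaired),
            "validated": "" if s.validated is None else int(s.validated),
        }
        for s in sorted(sites, key=_site_sort_key)
    ]
    cols = [
        "transcript", "start", "end", "mirna_id", "seed_mm", "tail_mm",
        "pos1_mismatch", "last_nt_unpaired", "validated",
    ]
    return pd.DataFrame(rows, columns=cols)


def write_sites_tsv(path: str | Path, sites: list[TargetSite]) -> None:
    sites_to_frame(sites).to_csv(path, sep="\t", index=False)


def write_sites_bed(path: str | Path, sites: list[TargetSite]) -> None:
    """BED6: 0-based half-open, score column carries seed+tail mismatches."""
    with open(path, "w") as handle:
        for s in sorted(sites, key=_site_sort_key):
            score = s.seed_mismatches + s.tail_mismatches
            handle.write(
                f"{s.transcript_id}\t{s.start}\t{s.end}\t{s.mirna_id}\t{score}\t-\n"
            )


def write_evidence_tsv(path: str | Path, evidence: list[CleavageEvidence]) -> None:
    rows = [
        {
            "mirna_id": e.site.mirna_id,
            "transcript": e.site.transcript_id,
            "site_start": e.site.start + 1,
            "site_end": e.site.end,
            "cleavage_coord": e.cleavage_coord + 1,
            "n_supporting": e.n_supporting,
            "verified": int(e.verified),
        }
        for e in sorted(evidence, key=lambda e: _site_sort_key(e.site))
    ]
    cols = [
        "mirna_id", "transcript", "site_start", "site_end",
        "cleavage_coord", "n_supporting", "verified",
    ]
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_cds_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """BED-like CDS intervals: transcript, cds_start, cds_end (0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    return {
        str(r.transcript): (int(r.cds_start), int(r.cds_end)) for _, r in df.iterrows()
    }


def write_cds_table(path: str | Path, cds: dict[str, tuple[int, int]]) -> None:
    rows = [
        {"transcript": t, "cds_start": a, "cds_end": b} for t, (a, b) in sorted(cds.items())
    ]
    pd.DataFrame(rows, columns=["transcript", "cds_start", "cds_end"]).to_csv(
        path, sep="\t", index=False
    )


def read_presence_matrix(path: str | Path) -> pd.DataFrame:
    """Presence/absence TSV: rows miRNA families, columns species, values 0/1."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_presence_matrix(path: str | Path, presence: pd.DataFrame) -> None:
    presence.to_csv(path, sep="\t")
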