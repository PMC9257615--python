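"""Reading campaign records and writing pipeline outputs.

Campaign input is either JSONL (one ``{"campaign_id": ..., "text": ...}``
object per line) or CSV with the same columns; the format is inferred from
the file extension.  Outputs are plain CSVs: a wide 0/1 assignment matrix
with per-category provenance columns, a long evidence table, and mention /
resolution logs mirroring the per-stage contracts.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .detector import Campaign, DiagnosisMention
from .lexicon import CATEGORIES
from .pipeline import to_wide


def read_campaigns(path: str | Path) -> list[Campaign]:
    """Load campaigns from JSONL or CSV (columns ``campaign_id,text``)."""
    path = Path(path)
    records: list[dict]
    if path.suffix.lower() in {".jsonl", ".json", ".ndjson"}:
        records = []
        with open(path, "r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                try:
                    records.append(json.loads(line))
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path}:{lineno}: invalid JSON line") from exc
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = df.to_dict("records")
    campaigns = []
    seen: set[str] = set()
    for i, rec in enumerate(records, start=1):
        if "campaign_id" not in rec or "text" not in rec:
            raise ValueError(f"{path}: record {i} lacks campaign_id/text fields")
        cid = str(rec["campaign_id"])
        if cid in seen:
            raise ValueError(f"{path}: duplicate campaign_id {cid!r} (record {i})")
        seen.add(cid)
        campaigns.append(Campaign(cid, str(rec["text"] if rec["text"] is not None else "")))
    return campaigns


def write_campaigns_jsonl(campaigns, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for c in campaigns:
            fh.write(json.dumps({"campaign_id": c.campaign_id, "text": c.text}) + "\n")


def write_assignments(assignments: pd.DataFrame, path: str | Path) -> None:
    """Wide assignment CSV: one 0/1 column and one source column per category."""
    wide = to_wide(assignments).reset_index()
    sources = assignments.pivot(
        index="campaign_id", columns="disease_category", values="source"
    )
    for cat in CATEGORIES:
        wide[f"{cat}_source"] = sources.loc[wide["campaign_id"], cat].fillna("").to_numpy()
    wide.to_csv(path, index=False)


def write_evidence(assignments: pd.DataFrame, path: str | Path) -> None:
    """Long-format evidence CSV (one row per piece of evidence)."""
    rows = []
    present = assignments[assignments["present"]]
    for rec in present.itertuples(index=False):
        for ev in rec.evidence:
            rows.append(
                {
                    "campaign_id": rec.campaign_id,
                    "disease_category": rec.disease_category,
                    "source": rec.source,
                    "evidence": ev,
                }
            )
    pd.DataFrame(rows, columns=["campaign_id", "disease_category", "source", "evidence"]).to_csv(
        path, index=False
    )


def write_mentions(mentions: list[DiagnosisMention], path: str | Path) -> None:
    """Mention CSV: ``campaign_id,start,end,surface,matched_term,edit_distance``."""
    pd.DataFrame(
        [
            {
                "campaign_id": m.campaign_id,
                "start": m.start,
                "end": m.end,
                "surface": m.surface,
                "matched_term": m.matched_term,
                "edit_distance": m.edit_distance,
            }
            for m in mentions
        ],
        columns=["campaign_id", "start", "end", "surface", "matched_term", "edit_distance"],
    ).to_csv(path, index=False)
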