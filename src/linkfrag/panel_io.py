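"""Flat-file serialization of design panels (TSV + BED).

The panel TSV is a single file with a ``kind`` column holding region, guide,
linker and fragment records; coordinates are 0-based half-open except the
human-facing ``position_1based`` column of guide records.
"""

from __future__ import annotations

import csv
from pathlib import Path

from .design import (
    DesignPanel,
    GuideCandidate,
    LinkerCandidate,
    PanelFragment,
    RegionDesign,
    TargetRegion,
)

__all__ = ["write_panel_tsv", "read_panel_tsv", "write_panel_bed"]

_FIELDS = [
    "kind",
    "id",
    "region",
    "contig",
    "start",
    "end",
    "strand",
    "protospacer",
    "pam",
    "nick_pos",
    "gc",
    "score",
    "position_1based",
    "guide_up",
    "guide_down",
    "left_linker",
    "right_linker",
]


def write_panel_tsv(panel: DesignPanel, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_FIELDS, delimiter="\t", restval="")
        writer.writeheader()
        for rd in panel.regions:
            rname = rd.region.name or rd.region.contig
            writer.writerow(
                {
                    "kind": "region",
                    "id": rname,
                    "region": rname,
                    "contig": rd.region.contig,
                    "start": rd.region.start,
                    "end": rd.region.end,
                }
            )
            seen_guides = set()
            for lk in rd.linkers:
                for g in (lk.guide_up, lk.guide_down):
                    if g.guide_id in seen_guides:
                        continue
                    seen_guides.add(g.guide_id)
                    writer.writerow(
                        {
                            "kind": "guide",
                            "id": g.guide_id,
                            "region": rname,
                            "contig": g.contig,
                            "start": g.start,
                            "end": g.end,
                            "strand": g.strand,
                            "protospacer": g.protospacer,
                            "pam": g.pam,
                            "nick_pos": g.nick_pos,
                            "gc": f"{g.gc:.3f}",
                            "score": f"{g.score:.4f}",
                            "position_1based": g.start + 1,
                        }
                    )
            for lk in rd.linkers:
                writer.writerow(
                    {
                        "kind": "linker",
                        "id": lk.linker_id,
                        "region": rname,
                        "contig": lk.contig,
                        "start": lk.start,
                        "end": lk.end,
                        "guide_up": lk.guide_up.guide_id,
                        "guide_down": lk.guide_down.guide_id,
                    }
                )
            for fr in rd.fragments:
                writer.writerow(
                    {
                        "kind": "fragment",
                        "id": fr.fragment_id,
                        "region": rname,
                        "contig": fr.contig,
                        "start": fr.start,
                        "end": fr.end,
                        "left_linker": fr.left_linker or "",
                        "right_linker": fr.right_linker or "",
                    }
                )


def read_panel_tsv(path: str | Path) -> DesignPanel:
    regions: dict[str, RegionDesign] = {}
    guides: dict[str, GuideCandidate] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh, delimiter="\t"))
    for row in rows:
        if row["kind"] == "region":
            tr = TargetRegion(
                contig=row["contig"],
                start=int(row["start"]),
                end=int(row["end"]),
                name=row["id"],
            )
            regions[row["id"]] = RegionDesign(tr, [], [], [])
            order.append(row["id"])
        elif row["kind"] == "guide":
            guides[row["id"]] = GuideCandidate(
                contig=row["contig"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
                protospacer=row["protospacer"],
                pam=row["pam"],
                nick_pos=int(row["nick_pos"]),
                gc=float(row["gc"]),
                score=float(row["score"]),
            )
    for row in rows:
        if row["kind"] == "linker":
            lk = LinkerCandidate(
                contig=row["contig"],
                start=int(row["start"]),
                end=int(row["end"]),
                guide_up=guides[row["guide_up"]],
                guide_down=guides[row["guide_down"]],
            )
            regions[row["region"]].linkers.append(lk)
        elif row["kind"] == "fragment":
            fr = PanelFragment(
                fragment_id=row["id"],
                contig=row["contig"],
                start=int(row["start"]),
                end=int(row["end"]),
                left_linker=row["left_linker"] or None,
                right_linker=row["right_linker"] or None,
            )
            regions[row["region"]].fragments.append(fr)
    return DesignPanel(regions=[regions[name] for name in order])


def write_panel_bed(panel: DesignPanel, path: str | Path) -> None:
    """Linkers and fragments as BED (0-based half-open)."""
    with open(path, "w") as fh:
        for lk in panel.linkers:
            fh.write(f"{lk.contig}\t{lk.start}\t{lk.end}\tlinker:{lk.linker_id}\n")
        for fr in panel.fragments:
            fh.write(f"{fr.contig}\t{fr.start}\t{fr.end}\tfragment:{fr.fragment_id}\n")
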