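"""Checklist of bamboo-feeding true bugs (BFTBs) of China.

The packaged fixture ``data/bftb_china_checklist.csv`` is a machine-readable
transcription of the published China checklist: 69 species in 9 families
across four heteropteran superfamilies (Miroidea, Lygaeoidea, Coreoidea,
Pentatomoidea).  Tribe assignments exist only for Coreoidea and are
annotation-derived (Alydidae are all Micrelytrini; within Coreidae,
Notobitus/Notobitiella/Cloresmus are Cloresmini and Manocoreus are
Manocoreini; Fracastorius and Homoeocerus sit outside these tribes).
Host-plant entries of "No record" are stored as empty lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "ChecklistEntry",
    "ChecklistError",
    "VALID_SUPERFAMILIES",
    "CHINA_FAMILIES",
    "packaged_checklist_path",
    "load_checklist",
    "summarize_checklist",
]

VALID_SUPERFAMILIES = frozenset({"Miroidea", "Lygaeoidea", "Coreoidea", "Pentatomoidea"})

#: The nine families of the China checklist table.
CHINA_FAMILIES = frozenset(
    {
        "Miridae",
        "Blissidae",
        "Heterogastridae",
        "Malcidae",
        "Berytidae",
        "Colobathristidae",
        "Alydidae",
        "Coreidae",
        "Pentatomidae",
    }
)

_REQUIRED_COLUMNS = [
    "species_name",
    "genus",
    "family",
    "superfamily",
    "tribe",
    "host_plants",
    "region",
]


class ChecklistError(ValueError):
    """Raised for schema or validation failures in a checklist file."""


@dataclass(frozen=True)
class ChecklistEntry:
    """One checklist row.

    ``host_plants`` is empty when the source table says "No record";
    ``region`` is ``china`` for the national checklist and ``global_only``
    for species recorded only outside China.
    """

    species_name: str
    genus: str
    family: str
    superfamily: str
    tribe: str = ""
    host_plants: tuple[str, ...] = field(default_factory=tuple)
    region: str = "china"


def packaged_checklist_path() -> Path:
    """Path of the packaged China checklist CSV."""
    return Path(str(resources.files("bftb_sdm").joinpath("data/bftb_china_checklist.csv")))


def load_checklist(path: str | Path | None = None) -> list[ChecklistEntry]:
    """Load and validate a checklist CSV.

    Parameters
    ----------
    path : optional
        CSV with columns ``species_name, genus, family, superfamily, tribe,
        host_plants, region`` (host plants semicolon-joined).  Defaults to
        the packaged China checklist.

    Raises
    ------
    ChecklistError
        On a missing column, a duplicate china species name, an unknown
        superfamily, a china entry outside the nine checklist families, or a
        tribe given for a non-Coreoidea entry.
    """
    if path is None:
        path = packaged_checklist_path()
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ChecklistError(f"checklist {path}: missing required column(s) {missing}")

    entries: list[ChecklistEntry] = []
    for _, row in df.iterrows():
        hosts_raw = row["host_plants"].strip()
        hosts = tuple(
            h.strip() for h in hosts_raw.split(";") if h.strip()
        ) if hosts_raw and hosts_raw.lower() != "no record" else ()
        entries.append(
            ChecklistEntry(
                species_name=row["species_name"].strip(),
                genus=row["genus"].strip(),
                family=row["family"].strip(),
                superfamily=row["superfamily"].strip(),
                tribe=row["tribe"].strip(),
                host_plants=hosts,
                region=row["region"].strip(),
            )
        )

    china = [e for e in entries if e.region == "china"]
    names = [e.species_name for e in china]
    dupes = {n for n in names if names.count(n) > 1}
    if dupes:
        raise ChecklistError(f"duplicate china species_name(s): {sorted(dupes)}")
    for e in entries:
        if e.superfamily not in VALID_SUPERFAMILIES:
            raise ChecklistError(
                f"{e.species_name}: unknown superfamily {e.superfamily!r}"
            )
        if e.region == "china" and e.family not in CHINA_FAMILIES:
            raise ChecklistError(
                f"{e.species_name}: family {e.family!r} not in the China checklist families"
            )
        if e.tribe and e.superfamily != "Coreoidea":
            raise ChecklistError(
                f"{e.species_name}: tribe set for non-Coreoidea entry"
            )
        if e.region not in {"china", "global_only"}:
            raise ChecklistError(f"{e.species_name}: bad region {e.region!r}")
    return entries


_LEVELS = {"family", "superfamily", "genus", "tribe"}


def summarize_checklist(
    entries: list[ChecklistEntry], level: str = "family"
) -> pd.DataFrame:
    """Count species and genera per taxonomic group.

    Returns a DataFrame with columns ``group, n_species, n_genera`` sorted
    by descending species count then group name.  Groups with zero members
    (e.g. the empty tribe of non-Coreoidea entries) are omitted.
    """
    if level not in _LEVELS:
        raise ValueError(f"unknown level {level!r}; expected one of {sorted(_LEVELS)}")
    rows: dict[str, tuple[set[str], set[str]]] = {}
    for e in entries:
        group = getattr(e, level if level != "genus" else "genus")
        if not group:
            continue
        species, genera = rows.setdefault(group, (set(), set()))
        species.add(e.species_name)
        genera.add(e.genus)
    table = pd.DataFrame(
        [
            {"group": g, "n_species": len(sp), "n_genera": len(ge)}
            for g, (sp, ge) in rows.items()
        ]
    )
    if table.empty:
        return pd.DataFrame(columns=["group", "n_species", "n_genera"])
    return (
        table.sort_values(["n_species", "group"], ascending=[False, True])
        .reset_index(drop=True)
    )
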