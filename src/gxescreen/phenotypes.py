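"""Derivation of childhood-adversity exposure and symptom phenotypes.

Childhood adversity is measured with the five-item Childhood Trauma
Screener (CTS-5).  Each item is answered on a five-level Likert scale
(0 = "Never true", 1 = "Rarely true", 2 = "Sometimes true", 3 = "Often",
4 = "Very often true").  The three abuse items (physical, emotional,
sexual abuse) are endorsed when the response is "Sometimes true" or more
frequent; the two neglect items (felt loved as a child, taken to the
doctor when needed) are reverse-keyed and endorsed when the response is
"Never true" or "Rarely true".  The binary exposure ``any_ace`` is 1 when
at least one item is endorsed, and ``ace_count`` (0-5) sums the endorsed
items.

Psychopathological symptoms are organised in a :class:`PhenotypeCatalog`:
binary symptom items grouped into domains, with domain endorsement defined
as "yes" to at least one member symptom.  A domain consisting of a single
symptom (help-seeking) counts as one distinct phenotype, so 55 symptoms
plus 7 domains yield 61 distinct phenotypes.  Continuous cognition scores
are dichotomised at a configurable impairment quantile.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CTS5_COLUMNS",
    "CTS5_LEVELS",
    "ACE_TYPES",
    "AceStatus",
    "AllItemsMissingError",
    "derive_ace",
    "derive_ace_table",
    "PhenotypeEntry",
    "PhenotypeCatalog",
    "build_catalog",
    "default_catalog",
    "derive_symptom",
    "derive_domain",
    "derive_phenotypes",
    "catalog_to_yaml",
    "catalog_from_yaml",
]

CTS5_LEVELS = {
    0: "Never true",
    1: "Rarely true",
    2: "Sometimes true",
    3: "Often",
    4: "Very often true",
}

#: adversity types in CTS-5 item order
ACE_TYPES = (
    "physical_abuse",
    "emotional_abuse",
    "sexual_abuse",
    "emotional_neglect",
    "physical_neglect",
)
_ABUSE = ACE_TYPES[:3]
_NEGLECT = ACE_TYPES[3:]

CTS5_COLUMNS = tuple(f"cts5_item_{i}" for i in range(1, 6))


class AllItemsMissingError(ValueError):
    """All five CTS-5 items are missing; the participant is not classifiable."""


@dataclass(frozen=True)
class AceStatus:
    """Adversity exposure for one participant.

    Type flags are ``None`` when the corresponding item was not answered;
    ``any_ace`` and ``ace_count`` are computed from the observed items only.
    """

    any_ace: int
    ace_count: int
    physical_abuse: Optional[int]
    emotional_abuse: Optional[int]
    sexual_abuse: Optional[int]
    emotional_neglect: Optional[int]
    physical_neglect: Optional[int]

    def flags(self) -> tuple[Optional[int], ...]:
        return (
            self.physical_abuse,
            self.emotional_abuse,
            self.sexual_abuse,
            self.emotional_neglect,
            self.physical_neglect,
        )


def _endorsed(code: float, ace_type: str) -> int:
    # abuse items keyed forward, neglect items reverse-keyed
    if ace_type in _ABUSE:
        return int(code >= 2)
    return int(code <= 1)


def derive_ace(items: Sequence[Optional[float]]) -> AceStatus:
    """Classify one participant's five CTS-5 responses.

    Parameters
    ----------
    items
        Five ordinal codes in CTS-5 item order (physical abuse, emotional
        abuse, sexual abuse, emotional neglect, physical neglect); ``None``
        or NaN marks a missing item.

    Raises
    ------
    AllItemsMissingError
        If every item is missing (such rows are excluded from analysis).
    ValueError
        If a non-missing code is outside 0..4.
    """
    if len(items) != 5:
        raise ValueError(f"expected 5 CTS-5 items, got {len(items)}")
    flags: list[Optional[int]] = []
    for value, ace_type in zip(items, ACE_TYPES):
        if value is None or (isinstance(value, float) and np.isnan(value)):
            flags.append(None)
            continue
        code = float(value)
        if code not in (0.0, 1.0, 2.0, 3.0, 4.0):
            raise ValueError(f"CTS-5 code {value!r} for {ace_type} outside levels 0-4")
        flags.append(_endorsed(code, ace_type))
    observed = [f for f in flags if f is not None]
    if not observed:
        raise AllItemsMissingError("all five CTS-5 items missing")
    return AceStatus(
        any_ace=int(any(f == 1 for f in observed)),
        ace_count=int(sum(observed)),
        physical_abuse=flags[0],
        emotional_abuse=flags[1],
        sexual_abuse=flags[2],
        emotional_neglect=flags[3],
        physical_neglect=flags[4],
    )


def derive_ace_table(
    cohort: pd.DataFrame,
    columns: Sequence[str] = CTS5_COLUMNS,
    id_column: str = "participant_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Vectorised ACE derivation over a cohort table.

    Returns
    -------
    derived : DataFrame
        One row per retained participant (index aligned with ``cohort``)
        with columns ``any_ace``, ``ace_count`` and the five type flags
        (NaN where the item was missing).
    exclusions : DataFrame
        Participants dropped because all five items were missing, with an
        exclusion reason.
    """
    values = cohort[list(columns)].to_numpy(dtype=float)
    observed = ~np.isnan(values)
    in_range = np.isnan(values) | (
        (values >= 0) & (values <= 4) & (values == np.floor(values))
    )
    if not in_range.all():
        bad = np.argwhere(~in_range)[0]
        raise ValueError(
            f"CTS-5 code {values[bad[0], bad[1]]!r} in column "
            f"{columns[bad[1]]} outside levels 0-4"
        )

    flags = np.full_like(values, np.nan)
    flags[:, :3] = np.where(observed[:, :3], (values[:, :3] >= 2).astype(float), np.nan)
    flags[:, 3:] = np.where(observed[:, 3:], (values[:, 3:] <= 1).astype(float), np.nan)

    all_missing = ~observed.any(axis=1)
    with np.errstate(invalid="ignore"):
        any_ace = (flags == 1).any(axis=1).astype(float)
        ace_count = np.nansum(flags, axis=1)

    derived = pd.DataFrame(
        {
            "any_ace": any_ace.astype(int),
            "ace_count": ace_count.astype(int),
            **{t: flags[:, i] for i, t in enumerate(ACE_TYPES)},
        },
        index=cohort.index,
    )
    derived = derived.loc[~all_missing]
    if id_column in cohort.columns:
        ids = cohort.loc[all_missing, id_column]
    else:
        ids = pd.Series(cohort.index[all_missing], index=cohort.index[all_missing])
    exclusions = pd.DataFrame(
        {"participant_id": ids, "reason": "all five CTS-5 items missing"}
    )
    return derived, exclusions


# ---------------------------------------------------------------------------
# Phenotype catalog
# ---------------------------------------------------------------------------

_RULES = ("direct", "ordinal_threshold", "quantile_impairment", "any_member")


@dataclass(frozen=True)
class PhenotypeEntry:
    """One binary phenotype: a symptom, a domain, or a single-symptom domain.

    ``members`` lists raw item columns for symptom-level entries and member
    symptom ``phenotype_id``s for domain-level entries.  ``level`` is
    ``"symptom"``, ``"domain"`` or ``"both"`` (a single-symptom domain, which
    is one distinct phenotype).
    """

    phenotype_id: str
    label: str
    domain: str
    level: str
    members: tuple[str, ...]
    rule: str = "direct"
    rule_params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.level not in ("symptom", "domain", "both"):
            raise ValueError(f"unknown level {self.level!r} for {self.phenotype_id}")
        if self.rule not in _RULES:
            raise ValueError(
                f"unregistered construction rule {self.rule!r} for {self.phenotype_id}"
            )
        if not self.members:
            raise ValueError(f"{self.phenotype_id} has no member columns")


@dataclass(frozen=True)
class PhenotypeCatalog:
    entries: tuple[PhenotypeEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.phenotype_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate phenotype ids: {dupes}")
        symptom_ids = {e.phenotype_id for e in self.entries if e.level in ("symptom", "both")}
        for e in self.entries:
            if e.level == "domain":
                unknown = [m for m in e.members if m not in symptom_ids]
                if unknown:
                    raise ValueError(
                        f"domain {e.phenotype_id} references unknown symptoms {unknown}"
                    )

    @property
    def symptoms(self) -> tuple[PhenotypeEntry, ...]:
        return tuple(e for e in self.entries if e.level in ("symptom", "both"))

    @property
    def domains(self) -> tuple[PhenotypeEntry, ...]:
        return tuple(e for e in self.entries if e.level in ("domain", "both"))

    @property
    def domain_names(self) -> tuple[str, ...]:
        seen: list[str] = []
        for e in self.entries:
            if e.domain not in seen:
                seen.append(e.domain)
        return tuple(seen)

    @property
    def n_symptoms(self) -> int:
        return len(self.symptoms)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    @property
    def n_phenotypes(self) -> int:
        """Distinct phenotypes (a single-symptom domain counts once)."""
        return len(self.entries)

    def get(self, phenotype_id: str) -> PhenotypeEntry:
        for e in self.entries:
            if e.phenotype_id == phenotype_id:
                return e
        raise KeyError(phenotype_id)

    def validate_standard(self) -> None:
        """Check the full-questionnaire shape: 55 symptoms, 7 domains, 61 phenotypes."""
        if self.n_symptoms != 55:
            raise ValueError(f"expected 55 symptom-level entries, found {self.n_symptoms}")
        if self.n_domains != 7:
            raise ValueError(f"expected 7 domains, found {self.n_domains}")
        if self.n_phenotypes != 61:
            raise ValueError(f"expected 61 distinct phenotypes, found {self.n_phenotypes}")


#: symptom counts per domain for the default catalog (52 questionnaire
#: symptoms across six domains plus 3 cognition tests = 55)
DEFAULT_DOMAIN_SIZES: Mapping[str, int] = {
    "psychotic": 10,
    "mania": 9,
    "depression": 14,
    "anxiety": 12,
    "self_harm": 6,
    "help_seeking": 1,
    "cognition": 3,
}


def build_catalog(
    domain_sizes: Mapping[str, int],
    continuous_domains: Sequence[str] = ("cognition",),
    impairment_quantile: float = 0.25,
) -> PhenotypeCatalog:
    """Construct a catalog with generic symptom labels.

    Each domain contributes ``domain_sizes[d]`` symptom entries backed by
    item columns ``item_<phenotype_id>`` plus one domain entry; a
    single-symptom domain collapses into one entry of level ``"both"``.
    Domains listed in ``continuous_domains`` use continuous item columns
    dichotomised at ``impairment_quantile`` (scores at or below the
    quantile are coded impaired).
    """
    entries: list[PhenotypeEntry] = []
    domain_entries: list[PhenotypeEntry] = []
    for domain, size in domain_sizes.items():
        if size < 1:
            raise ValueError(f"domain {domain} must have at least one symptom")
        rule = "quantile_impairment" if domain in continuous_domains else "direct"
        params = {"quantile": impairment_quantile} if rule == "quantile_impairment" else {}
        if size == 1:
            entries.append(
                PhenotypeEntry(
                    phenotype_id=domain,
                    label=domain.replace("_", " "),
                    domain=domain,
                    level="both",
                    members=(f"item_{domain}",),
                    rule=rule,
                    rule_params=params,
                )
            )
            continue
        member_ids = []
        for i in range(1, size + 1):
            pid = f"{domain}_{i:02d}"
            member_ids.append(pid)
            entries.append(
                PhenotypeEntry(
                    phenotype_id=pid,
                    label=f"{domain.replace('_', ' ')} symptom {i}",
                    domain=domain,
                    level="symptom",
                    members=(f"item_{pid}",),
                    rule=rule,
                    rule_params=params,
                )
            )
        domain_entries.append(
            PhenotypeEntry(
                phenotype_id=f"dom_{domain}",
                label=f"{domain.replace('_', ' ')} domain",
                domain=domain,
                level="domain",
                members=tuple(member_ids),
                rule="any_member",
            )
        )
    return PhenotypeCatalog(entries=tuple(entries + domain_entries))


def default_catalog(impairment_quantile: float = 0.25) -> PhenotypeCatalog:
    """The 61-phenotype catalog (55 symptoms, 7 domains, shared help-seeking)."""
    return build_catalog(DEFAULT_DOMAIN_SIZES, impairment_quantile=impairment_quantile)


# ---------------------------------------------------------------------------
# Phenotype derivation
# ---------------------------------------------------------------------------


def derive_symptom(cohort: pd.DataFrame, entry: PhenotypeEntry) -> pd.Series:
    """Dichotomise one symptom; missing item responses propagate as NaN."""
    if entry.rule == "direct":
        x = cohort[entry.members[0]].astype(float)
        bad = x.dropna()[~x.dropna().isin([0.0, 1.0])]
        if len(bad):
            raise ValueError(
                f"direct item {entry.members[0]} has non-binary value {bad.iloc[0]!r}"
            )
        return x
    if entry.rule == "ordinal_threshold":
        x = cohort[entry.members[0]].astype(float)
        cut = float(entry.rule_params["threshold"])
        return pd.Series(np.where(x.isna(), np.nan, (x >= cut).astype(float)), index=x.index)
    if entry.rule == "quantile_impairment":
        x = cohort[entry.members[0]].astype(float)
        q = float(entry.rule_params.get("quantile", 0.25))
        cut = np.nanquantile(x.to_numpy(), q)
        return pd.Series(np.where(x.isna(), np.nan, (x <= cut).astype(float)), index=x.index)
    raise ValueError(f"unregistered construction rule {entry.rule!r}")


def derive_domain(member_values: pd.DataFrame) -> pd.Series:
    """Domain endorsement: 1 if any member symptom is 1, 0 if all observed
    members are 0, missing only when every member is missing."""
    if member_values.shape[1] < 1:
        raise ValueError("domain needs at least one member symptom")
    arr = member_values.to_numpy(dtype=float)
    any_yes = (arr == 1).any(axis=1)
    all_missing = np.isnan(arr).all(axis=1)
    out = np.where(any_yes, 1.0, 0.0)
    out = np.where(all_missing, np.nan, out)
    return pd.Series(out, index=member_values.index)


def derive_phenotypes(cohort: pd.DataFrame, catalog: PhenotypeCatalog) -> pd.DataFrame:
    """Derive every catalog phenotype as a binary column named by phenotype_id."""
    out = pd.DataFrame(index=cohort.index)
    for entry in catalog.entries:
        if entry.level in ("symptom", "both"):
            out[entry.phenotype_id] = derive_symptom(cohort, entry)
    for entry in catalog.entries:
        if entry.level == "domain":
            out[entry.phenotype_id] = derive_domain(out[list(entry.members)])
    return out


# ---------------------------------------------------------------------------
# Catalog serialization
# ---------------------------------------------------------------------------


def catalog_to_yaml(catalog: PhenotypeCatalog, path: str) -> None:
    payload = [
        {
            "phenotype_id": e.phenotype_id,
            "label": e.label,
            "domain": e.domain,
            "level": e.level,
            "members": list(e.members),
            "rule": e.rule,
            "rule_params": dict(e.rule_params),
        }
        for e in catalog.entries
    ]
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def catalog_from_yaml(path: str) -> PhenotypeCatalog:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    entries = tuple(
        PhenotypeEntry(
            phenotype_id=d["phenotype_id"],
            label=d.get("label", d["phenotype_id"]),
            domain=d["domain"],
            level=d["level"],
            members=tuple(d["members"]),
            rule=d.get("rule", "direct"),
            rule_params=d.get("rule_params", {}) or {},
        )
        for d in payload
    )
    return PhenotypeCatalog(entries=entries)
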