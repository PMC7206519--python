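"""The fixed-length term vector space shared by patients and documents.

Each dimension is a term describing both a patient characteristic and a
document topic (hypertension, blood pressure, depression, ...).  Patients
are projected into the space by severity rules, documents by keyword /
embedding similarity; the inner product of the two projections scores the
pair.  The default space ships 33 terms; the space is configuration, not
code, and any label list can be loaded from YAML/JSON.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

#: Default 33-term space: chronic-disease conditions, measurable risk
#: factors, lifestyle factors, demographics, and drug/education topics.
DEFAULT_TERMS: tuple[str, ...] = (
    "hypertension", "diabetes", "stroke", "hyperlipidemia",
    "coronary artery disease", "copd", "other disease",
    "blood pressure", "blood glucose", "total cholesterol", "triglyceride",
    "hdl", "ldl", "uric acid", "bmi",
    "smoking", "drinking", "diet", "physical activity", "depression",
    "pregnancy", "female", "male", "age",
    "antihypertensive drug", "hypoglycemic drug", "hypolipidemic drug",
    "medication adherence",
    "salt intake", "weight control", "exercise", "sleep", "mental health",
)


@dataclass
class VectorSpace:
    terms: tuple[str, ...] = DEFAULT_TERMS
    #: per-term alternative surfaces to try when resolving embeddings
    aliases: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = tuple(self.terms)
        if len(self.terms) == 0:
            raise ValueError("vector space needs at least one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("vector-space term labels must be distinct")
        unknown = set(self.aliases) - set(self.terms)
        if unknown:
            raise ValueError(f"aliases for unknown terms: {sorted(unknown)}")

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term: str) -> bool:
        return term in self.terms

    def index(self, term: str) -> int:
        return self.terms.index(term)

    def surfaces_for(self, term: str) -> list[str]:
        """Candidate token surfaces for a term: the label itself, the label
        with spaces removed (compound form), then configured aliases."""
        out = [term]
        compact = term.replace(" ", "")
        if compact != term:
            out.append(compact)
        out.extend(self.aliases.get(term, []))
        return out

    def to_yaml(self) -> str:
        return yaml.safe_dump({"terms": list(self.terms),
                               "aliases": {k: list(v) for k, v in self.aliases.items()}},
                              sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, text: str) -> "VectorSpace":
        data = yaml.safe_load(text)
        if isinstance(data, list):
            return cls(tuple(data))
        return cls(tuple(data["terms"]), dict(data.get("aliases", {})))


def default_space() -> VectorSpace:
    return VectorSpace(DEFAULT_TERMS)
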