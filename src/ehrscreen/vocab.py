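"""Miniature hierarchical clinical-code vocabulary.

A stand-in for a SNOMED-CT-like terminology: codes form a directed acyclic
parent->child hierarchy in which a parent concept subsumes its descendants,
and every code carries exactly one role tag describing how it participates
in the caseness phenotype (inclusion diagnosis, exclusion diagnosis,
generic psychiatric, antecedent-type, concurrent-type, referral-type,
other/somatic).

The default vocabulary mirrors the published inclusion/exclusion parent
concepts (borderline personality disorder, dysthymia, chronic and complex
post-traumatic stress disorder, persistent depressive disorder;
schizophrenia, bipolar disorder, dementia) and the named medications of
interest, padded with a synthetic set of generic psychiatric, somatic,
antecedent and concurrent codes so that every pipeline stage is exercised.
Synthetic identifiers are prefixed (``MH-``, ``SOM-``) to distinguish them
from real concept identifiers.
"""
from __future__ import annotations

from dataclasses import dataclass, field


class CodelistError(KeyError):
    """Raised when a codelist refers to a code absent from the vocabulary."""


ROLES = (
    "inclusion",
    "exclusion",
    "generic_psychiatric",
    "antecedent",
    "concurrent",
    "referral",
    "other",
)


@dataclass(frozen=True)
class Code:
    code: str
    label: str
    role: str
    parents: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r} for code {self.code}")


@dataclass
class CodeVocabulary:
    """A DAG of clinical codes with per-code role tags."""

    codes: dict[str, Code] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._children: dict[str, list[str]] = {c: [] for c in self.codes}
        for c in self.codes.values():
            for p in c.parents:
                if p not in self.codes:
                    raise CodelistError(f"parent {p!r} of {c.code!r} not in vocabulary")
                self._children[p].append(c.code)
        self._assert_acyclic()

    def _assert_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(c: str) -> None:
            state[c] = 1
            for ch in self._children[c]:
                s = state.get(ch)
                if s == 1:
                    raise ValueError(f"cycle in code hierarchy at {ch!r}")
                if s is None:
                    visit(ch)
            state[c] = 2

        for c in self.codes:
            if c not in state:
                visit(c)

    def __contains__(self, code: str) -> bool:
        return code in self.codes

    def __len__(self) -> int:
        return len(self.codes)

    def children(self, code: str) -> list[str]:
        return list(self._children[code])

    def descendants(self, root: str) -> frozenset[str]:
        """The root plus all transitive descendants."""
        if root not in self.codes:
            raise CodelistError(f"unknown code {root!r}")
        seen = {root}
        stack = [root]
        while stack:
            for ch in self._children[stack.pop()]:
                if ch not in seen:
                    seen.add(ch)
                    stack.append(ch)
        return frozenset(seen)

    def codes_with_role(self, role: str) -> list[str]:
        if role not in ROLES:
            raise ValueError(f"unknown role {role!r}")
        return sorted(c.code for c in self.codes.values() if c.role == role)

    def roots_with_role(self, role: str) -> list[str]:
        return sorted(
            c.code
            for c in self.codes.values()
            if c.role == role and not c.parents
        )


# medication name lists of the caseness definition; searched by name
ANTIDEPRESSANTS = (
    "Clomipramine", "Citalopram", "Duloxetine", "Escitalopram", "Mirtazapine",
    "Paroxetine", "Sertraline", "Trazodone", "Venlafaxine", "Fluoxetine",
)
ANTIPSYCHOTICS = (
    "Risperidone", "Olanzapine", "Quetiapine", "Flupentixol",
    "Chlorpromazine", "Aripiprazole", "Haloperidol",
)
HYPNOTICS_ANXIOLYTICS = ("Diazepam", "Zopiclone")

MEDICATION_CLASSES: dict[str, tuple[str, ...]] = {
    "antidepressant": ANTIDEPRESSANTS,
    "antipsychotic": ANTIPSYCHOTICS,
    "hypnotic_anxiolytic": HYPNOTICS_ANXIOLYTICS,
}

MEDICATIONS_OF_INTEREST: tuple[str, ...] = (
    ANTIDEPRESSANTS + ANTIPSYCHOTICS + HYPNOTICS_ANXIOLYTICS
)

# unrelated products, used as noise by the synthetic generator
OTHER_MEDICATIONS = ("Amoxicillin", "Atorvastatin", "Metformin", "Salbutamol")

MENTAL_DISORDER_ROOT = "74732009"

_GENERIC_LABELS = [
    "Depressive disorder", "Anxiety disorder", "Generalized anxiety disorder",
    "Panic disorder", "Obsessive-compulsive disorder",
    "Post-traumatic stress disorder", "Social phobia", "Agoraphobia",
    "Adjustment disorder", "Somatization disorder", "Insomnia disorder",
    "Eating disorder", "Anorexia nervosa", "Bulimia nervosa",
    "Attention deficit hyperactivity disorder", "Autism spectrum disorder",
    "Mixed anxiety and depressive disorder", "Seasonal affective disorder",
    "Health anxiety disorder", "Acute stress reaction", "Phobic disorder",
    "Dissociative disorder", "Body dysmorphic disorder", "Recurrent brief depression",
]

_SOMATIC_LABELS = [
    "Asthma", "Type 2 diabetes mellitus", "Essential hypertension",
    "Osteoarthritis", "Irritable bowel syndrome", "Migraine",
    "Hypothyroidism", "Chronic low back pain",
]

_ANTECEDENT_LABELS = [
    "History of child abuse", "History of childhood neglect",
    "Conduct disorder in childhood", "Parental separation in childhood",
    "Looked-after child", "School exclusion",
]

_CONCURRENT_LABELS = [
    "Self-harm", "Suicidal ideation", "Harmful alcohol use",
    "Substance misuse", "Drug dependence", "Medication overdose",
]


def default_vocabulary() -> CodeVocabulary:
    """Build the miniature default vocabulary.

    The generic psychiatric codes (and the inclusion and exclusion concepts)
    hang under the mental-disorder root so that descendant closure of that
    root recovers every psychiatric diagnosis, as in the full terminology.
    Antecedent and concurrent codes are findings/events outside it.
    """
    codes: list[Code] = [Code(MENTAL_DISORDER_ROOT, "Mental disorder", "generic_psychiatric")]

    root = (MENTAL_DISORDER_ROOT,)
    # inclusion concepts; personality disorder subsumes borderline PD
    codes += [
        Code("33449004", "Personality disorder", "inclusion", root),
        Code("20010003", "Borderline personality disorder", "inclusion", ("33449004",)),
        Code("MH-PD-HIST", "Histrionic personality disorder", "inclusion", ("33449004",)),
        Code("78667006", "Dysthymia", "inclusion", root),
        Code("1153575004", "Persistent depressive disorder", "inclusion", root),
        Code("192080009", "Chronic depression", "inclusion", root),
        Code("313182004", "Chronic post-traumatic stress disorder", "inclusion", root),
        Code("443919007", "Complex posttraumatic stress disorder", "inclusion", root),
    ]
    # exclusion concepts (severe mental illness and dementia)
    codes += [
        Code("58214004", "Schizophrenia", "exclusion", root),
        Code("MH-SCZ-PAR", "Paranoid schizophrenia", "exclusion", ("58214004",)),
        Code("13746004", "Bipolar disorder", "exclusion", root),
        Code("MH-BIP-II", "Bipolar II disorder", "exclusion", ("13746004",)),
        Code("MH-DEM", "Dementia", "exclusion", root),
        Code("MH-DEM-ALZ", "Alzheimer dementia", "exclusion", ("MH-DEM",)),
    ]
    for i, label in enumerate(_GENERIC_LABELS, start=1):
        codes.append(Code(f"MH-GEN-{i:02d}", label, "generic_psychiatric", root))
    for i, label in enumerate(_SOMATIC_LABELS, start=1):
        codes.append(Code(f"SOM-{i:02d}", label, "other"))
    for i, label in enumerate(_ANTECEDENT_LABELS, start=1):
        codes.append(Code(f"MH-ANT-{i:02d}", label, "antecedent"))
    for i, label in enumerate(_CONCURRENT_LABELS, start=1):
        codes.append(Code(f"MH-CON-{i:02d}", label, "concurrent"))
    codes.append(Code("REF-IAPT", "Referral to psychological therapy service", "referral"))
    return CodeVocabulary({c.code: c for c in codes})
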