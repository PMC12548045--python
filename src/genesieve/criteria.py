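"""The fixed eight-criterion evaluation scheme for sepsis relevance.

Each gene is judged against eight independent criteria covering disease
mechanism, immunology, biomarker utility and druggability.  Criterion
ids are stable snake_case keys; phrases are the human-readable wording
injected into prompts; keywords are the single retrieval-query terms
used when searching the literature index for a (gene, criterion) pair.
"""

from __future__ import annotations

CRITERIA: tuple[str, ...] = (
    "pathogenesis_association",
    "host_immune_response",
    "organ_dysfunction",
    "circulating_leukocyte_biology",
    "clinical_biomarker_use",
    "blood_transcriptional_biomarker_potential",
    "drug_target_status",
    "therapeutic_relevance",
)

N_CRITERIA: int = len(CRITERIA)

CRITERION_PHRASES: dict[str, str] = {
    "pathogenesis_association": "association with sepsis pathogenesis",
    "host_immune_response": "role in the host immune response",
    "organ_dysfunction": "involvement in sepsis-related organ dysfunction",
    "circulating_leukocyte_biology": "relevance to circulating leukocyte biology",
    "clinical_biomarker_use": "current use as a clinical biomarker",
    "blood_transcriptional_biomarker_potential":
        "potential as a blood transcriptional biomarker",
    "drug_target_status": "status as a drug target",
    "therapeutic_relevance": "therapeutic relevance in sepsis",
}

CRITERION_KEYWORDS: dict[str, str] = {
    "pathogenesis_association": "pathogenesis",
    "host_immune_response": "immune",
    "organ_dysfunction": "organ dysfunction",
    "circulating_leukocyte_biology": "leukocyte",
    "clinical_biomarker_use": "biomarker",
    "blood_transcriptional_biomarker_potential": "transcriptional",
    "drug_target_status": "drug target",
    "therapeutic_relevance": "therapeutic",
}


def validate_criterion(criterion: str) -> str:
    if criterion not in CRITERIA:
        raise ValueError(f"unknown criterion: {criterion!r}")
    return criterion
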