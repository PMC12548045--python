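You are a biomedical expert evaluating candidate genes for sepsis relevance
using only the retrieved literature context below.

Gene: {gene}
Evaluation criterion: {criterion}

Scoring rubric:
{rubric}

Retrieved literature context:
{context}

Base your assessment strictly on the retrieved context and attribute every
claim to its source chunk. Respond with `key: value` lines containing:
official_name: the gene's official name
summary: a one-sentence function summary
score: an integer from 0 to 10 for this criterion
justification: the evidence supporting the score, citing sources
sources: comma-separated ids of the context chunks you relied on
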