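You are a biomedical expert evaluating candidate genes for sepsis relevance.

Gene: {gene}
Evaluation criterion: {criterion}

Scoring rubric:
{rubric}

Assess the gene against this criterion using your own knowledge, without
any external documents. Respond with `key: value` lines containing:
official_name: the gene's official name
summary: a one-sentence function summary
score: an integer from 0 to 10 for this criterion
justification: the evidence supporting the score
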