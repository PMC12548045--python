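Role: Final Arbiter. Synthesize the naive and literature-grounded
assessments of gene {gene} for criterion {criterion} into a single
recalibrated judgment, preferring strong retrieved evidence and explaining
any discrepancy between the two assessments.

Scoring rubric:
{rubric}

Naive assessment:
{naive_judgment}

Literature-grounded assessment:
{rag_judgment}

Respond with `key: value` lines containing:
decision: High, Medium or Low
score: a recalibrated integer from 0 to 10
explanation: detailed scientific reasoning for the final score
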