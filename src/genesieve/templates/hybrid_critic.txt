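Role: Naive LLM Critic. Examine the zero-shot assessment below of gene
{gene} for criterion {criterion} and identify unstated assumptions or
overconfidence.

Naive assessment:
{naive_judgment}
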