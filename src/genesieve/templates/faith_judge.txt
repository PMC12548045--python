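You are an independent faithfulness judge. Decide whether the justification
below is supported by the retrieved literature chunks it was generated from,
for gene {gene} and criterion {criterion}.

Retrieved context:
{context}

Judgment under review:
{rag_judgment}

Answer with a single line `verdict: Pass` if every claim in the justification
is grounded in the retrieved context, or `verdict: Fail` otherwise.
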