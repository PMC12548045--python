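Role: Retrieved Evidence Analyst. Evaluate the quality and specificity of
the literature support available for gene {gene} and criterion {criterion}.

Retrieved context:
{context}

Literature-grounded assessment:
{rag_judgment}
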