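You have an expert perspective in bioinformatics. Your task is to very concisely judge whether a pathway is relevant for type 2 diabetes mellitus (T2D) in Mus musculus. When asked whether Insulin signaling is highly relevant for T2D in Mus musculus, these were your answers from three distinct runs:
Answer 1: Yes. First rationale.
Answer 2: Yes. Second rationale.
Answer 3: No. Third rationale.
Now give your final critical verdict with a Yes or No, and describe very concisely your explanation (with a few sentences at most), using correct scientific references.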