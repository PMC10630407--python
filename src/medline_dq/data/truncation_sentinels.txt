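# NLM abstract-truncation sentinel phrases (one per line, matched at end of abstract)
(ABSTRACT TRUNCATED)
(ABSTRACT TRUNCATED AT 250 WORDS)
(ABSTRACT TRUNCATED AT 400 WORDS)
(ABSTRACT TRUNCATED AT 10000 CHARACTERS)
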