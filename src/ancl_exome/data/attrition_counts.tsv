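# Published per-sample coding-SNS counts at each cascade stage.  The raw
# exomes are private: these counts are inputs to the attrition arithmetic,
# not quantities the package can recompute.
# shared_both / unique_to_cases / after_panel are set-level counts (reported
# once, on the affected-pair intersection).
sample	role	total_coding	nonsynonymous	after_filtering	shared_both	unique_to_cases	after_panel
case1	affected	38142	9202	674	96	24	19
case2	affected	38276	9285	636	.	.	.
control	unaffected	38120	9177	711	.	.	.
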