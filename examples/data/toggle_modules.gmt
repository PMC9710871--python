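module_a	genes co-regulated with core gene 1	core_a	resp_a_0	resp_a_1	resp_a_2	resp_a_3	resp_a_4	resp_a_5
module_b	genes co-regulated with core gene 2	core_b	resp_b_0	resp_b_1	resp_b_2	resp_b_3	resp_b_4	resp_b_5
housekeeping	fate-uninformative genes	null_0	null_1	null_2	null_3	null_4	null_5
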