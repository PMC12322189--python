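condition_id,nominal_delay,actual_delay_days,cp_culprit,cp_filler,cp_reject,ca_suspect,ca_filler,ca_reject
no_delay,none,0,401,276,423,133,383,584
one_day,1 day,1,265,355,444,137,397,530
one_week,1 week,8,188,359,493,117,396,527
one_month,1 month,33,134,347,531,109,370,533
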