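item,group,improved,same,worse
Understanding of intervention,intervention_under_scrutiny,4,4,0
Access to evidence on intervention,intervention_under_scrutiny,2,6,0
Access to quality assessment of evidence on intervention,intervention_under_scrutiny,4,4,0
Considering all key elements of decision,deliberative_process,4,4,0
Expressing personal/expert opinion,deliberative_process,1,8,0
Sharing & discussing values among committee members,deliberative_process,2,7,0
Transparency of decision,communication_of_decision,5,4,0
Understandability of decision by stakeholders,communication_of_decision,5,4,0
Acceptability of decision by stakeholders,communication_of_decision,3,4,0
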