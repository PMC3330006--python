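item,group,always,sometimes,never
Adherence to requirements of decision making body,mcda_matrix,3,6,0
Completeness and consistency of reporting evidence,mcda_matrix,8,1,0
Relevance and validity of evidence,mcda_matrix,8,1,0
Disease severity,mcda_matrix,8,1,0
Size of population affected by disease,mcda_matrix,6,3,0
Current clinical guidelines,mcda_matrix,8,1,0
Current interventions limitations,mcda_matrix,7,2,0
Improvement of efficacy/effectiveness,mcda_matrix,8,1,0
Improvement of safety & tolerability,mcda_matrix,7,2,0
"Improvement of PRO, convenience & adherence",mcda_matrix,4,5,0
Public health interest (prevention & risk reduction),mcda_matrix,7,2,0
Type of medical service,mcda_matrix,8,1,0
Budget impact on health plan,mcda_matrix,9,0,0
Cost-effectiveness of intervention,mcda_matrix,8,1,0
Impact on other spending,mcda_matrix,7,2,0
Appropriate use,other,8,1,0
Opportunity costs,other,7,2,0
Organizational structure,other,2,7,0
Stakeholder pressures,other,3,6,0
Political context,other,1,8,0
Population priorities and access,other,2,7,0
Regulatory status of intervention,other,5,4,0
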