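criterion_id,level_label,value_percent
patient_needs,Does not address patient needs,0
patient_needs,Moderately addresses patient needs,10.4
patient_needs,Highly addresses patient needs,17.6
cost,Expensive,0
cost,Neither expensive nor cheap,6.2
cost,Cheap,11.5
adaptability,Less adaptable,0
adaptability,Moderately adaptable,5.4
adaptability,Highly adaptable,9.8
priority,Low priority,0
priority,Medium priority,4.5
priority,High priority,8.7
advantage,Low advantage,0
advantage,Medium advantage,4.5
advantage,High advantage,8.1
resources,Less available,0
resources,Moderately available,4.4
resources,Highly available,8.6
evidence,Low evidence,0
evidence,Moderate evidence,6.0
evidence,Strong evidence,10.5
knowledge,Negative attitude,0
knowledge,Neither positive nor negative attitude,4.5
knowledge,Positive attitude,8.7
identification,Not well known in the organisation,0
identification,Moderately known in the organisation,4.8
identification,Highly known in the organisation,8.7
planning,Not well planned,0
planning,Moderately planned,4.3
planning,Well planned,7.8
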