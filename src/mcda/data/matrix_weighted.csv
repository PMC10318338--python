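alternative,criterion_id,level_label
Computerised Interface,patient_needs,Highly addresses patient needs
Computerised Interface,cost,Cheap
Computerised Interface,adaptability,Highly adaptable
Computerised Interface,priority,Medium priority
Computerised Interface,advantage,Medium advantage
Computerised Interface,resources,Highly available
Computerised Interface,evidence,Moderate evidence
Computerised Interface,knowledge,Positive attitude
Computerised Interface,identification,Moderately known in the organisation
Computerised Interface,planning,Well planned
Built Environment,patient_needs,Highly addresses patient needs
Built Environment,cost,Cheap
Built Environment,adaptability,Highly adaptable
Built Environment,priority,Medium priority
Built Environment,advantage,Medium advantage
Built Environment,resources,Moderately available
Built Environment,evidence,Moderate evidence
Built Environment,knowledge,Positive attitude
Built Environment,identification,Moderately known in the organisation
Built Environment,planning,Well planned
Written Communication,patient_needs,Highly addresses patient needs
Written Communication,cost,Cheap
Written Communication,adaptability,Highly adaptable
Written Communication,priority,Medium priority
Written Communication,advantage,Low advantage
Written Communication,resources,Moderately available
Written Communication,evidence,Moderate evidence
Written Communication,knowledge,Positive attitude
Written Communication,identification,Moderately known in the organisation
Written Communication,planning,Moderately planned
Face-to-Face,patient_needs,Highly addresses patient needs
Face-to-Face,cost,Expensive
Face-to-Face,adaptability,Moderately adaptable
Face-to-Face,priority,Medium priority
Face-to-Face,advantage,High advantage
Face-to-Face,resources,Less available
Face-to-Face,evidence,Strong evidence
Face-to-Face,knowledge,Positive attitude
Face-to-Face,identification,Highly known in the organisation
Face-to-Face,planning,Moderately planned
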