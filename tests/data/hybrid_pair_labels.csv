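,POP1/C116A,POP1/J2416,POP1/EH,POP2/C116A,POP2/Z58,POP2/C2404,POP3/C116A,POP3/Z58,POP3/J2416,POP4/C116A,POP4/J2416,POP4/C783,POP5/C229,POP5/C2404,POP5/Z58
POP1/C116A,In_Group,Same_DH,Same_DH,Same_Tester,M1,M1,Same_Tester,M1,M1,Same_Tester,M1,M2,Tri_Group,Tri_Group,Tri_Group
POP1/J2416,Same_DH,In_Group,Same_DH,M1,M1,M1,M1,M1,Same_Tester,M1,Same_Tester,M2,Tri_Group,Tri_Group,Tri_Group
POP1/EH,Same_DH,Same_DH,In_Group,M1,Tri_Group,Tri_Group,M2,Tri_Group,M2,M1,M1,Tri_Group,M2,M1,M1
POP2/C116A,Same_Tester,M1,M1,In_Group,Same_DH,Same_DH,Same_Tester,M1,Tri_Group,Same_Tester,M1,M2,M2,M2,M2
POP2/Z58,M1,M1,Tri_Group,Same_DH,In_Group,Same_DH,M1,Same_Tester,M1,M1,M1,Tri_Group,M1,M1,Same_Tester
POP2/C2404,M1,M1,Tri_Group,Same_DH,Same_DH,In_Group,M1,Tri_Group,M1,M1,M1,Tri_Group,M1,Same_Tester,M1
POP3/C116A,Same_Tester,M1,M2,Same_Tester,M1,M1,In_Group,Same_DH,Same_DH,Same_Tester,M0,M1,M2,M2,M2
POP3/Z58,M1,M1,Tri_Group,M1,Same_Tester,Tri_Group,Same_DH,In_Group,Same_DH,M0,M0,Tri_Group,M1,M1,Same_Tester
POP3/J2416,M1,Same_Tester,M2,Tri_Group,M1,M1,Same_DH,Same_DH,In_Group,M0,Same_Tester,M1,M1,M1,M1
POP4/C116A,Same_Tester,M1,M1,Same_Tester,M1,M1,Same_Tester,M0,M0,In_Group,Same_DH,Same_DH,M2,M1,M1
POP4/J2416,M1,Same_Tester,M1,M1,M1,M1,M0,M0,Same_Tester,Same_DH,In_Group,Same_DH,M1,M0,M0
POP4/C783,M2,M2,Tri_Group,M2,Tri_Group,Tri_Group,M1,Tri_Group,M1,Same_DH,Same_DH,In_Group,M2,M1,M1
POP5/C229,Tri_Group,Tri_Group,M2,M2,M1,M1,M2,M1,M1,M2,M1,M2,In_Group,Same_DH,Same_DH
POP5/C2404,Tri_Group,Tri_Group,M1,M2,M1,Same_Tester,M2,M1,M1,M1,M0,M1,Same_DH,In_Group,Same_DH
POP5/Z58,Tri_Group,Tri_Group,M1,M2,Same_Tester,M1,M2,Same_Tester,M1,M1,M0,M1,Same_DH,Same_DH,In_Group
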