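reporter,reported,candidate,sex
father,father,grandparent,m
father,mother,grandparent,f
father,sibling,aunt_uncle,any
father,grandparent,other,any
father,aunt_uncle,grandparent,any
father,godparent,other,any
father,cousin,aunt_uncle,any
father,child,ego,any
father,child,sibling,any
father,niece_nephew,cousin,any
father,grandchild,child,any
father,grandchild,niece_nephew,any
father,spouse_partner,father,m
father,spouse_partner,mother,f
father,parent_in_law,grandparent,any
father,sibling_in_law,aunt_uncle,any
father,child_in_law,spouse_partner,any
father,child_in_law,sibling_in_law,any
mother,father,grandparent,m
mother,mother,grandparent,f
mother,sibling,aunt_uncle,any
mother,grandparent,other,any
mother,aunt_uncle,grandparent,any
mother,godparent,other,any
mother,cousin,aunt_uncle,any
mother,child,ego,any
mother,child,sibling,any
mother,niece_nephew,cousin,any
mother,grandchild,child,any
mother,grandchild,niece_nephew,any
mother,spouse_partner,father,m
mother,spouse_partner,mother,f
mother,parent_in_law,grandparent,any
mother,sibling_in_law,aunt_uncle,any
mother,child_in_law,spouse_partner,any
mother,child_in_law,sibling_in_law,any
sibling,father,father,m
sibling,mother,mother,f
sibling,sibling,ego,any
sibling,sibling,sibling,any
sibling,grandparent,grandparent,any
sibling,aunt_uncle,aunt_uncle,any
sibling,godparent,godparent,any
sibling,cousin,cousin,any
sibling,child,niece_nephew,any
sibling,niece_nephew,child,any
sibling,niece_nephew,niece_nephew,any
sibling,grandchild,grandchild,any
sibling,spouse_partner,sibling_in_law,any
sibling,parent_in_law,other,any
sibling,sibling_in_law,spouse_partner,any
sibling,sibling_in_law,sibling_in_law,any
sibling,child_in_law,other,any
grandparent,father,other,any
grandparent,mother,other,any
grandparent,sibling,grandparent,any
grandparent,grandparent,other,any
grandparent,aunt_uncle,other,any
grandparent,godparent,other,any
grandparent,cousin,grandparent,any
grandparent,child,father,m
grandparent,child,mother,f
grandparent,child,aunt_uncle,any
grandparent,niece_nephew,aunt_uncle,any
grandparent,grandchild,ego,any
grandparent,grandchild,sibling,any
grandparent,grandchild,cousin,any
grandparent,spouse_partner,grandparent,any
grandparent,parent_in_law,other,any
grandparent,sibling_in_law,grandparent,any
grandparent,child_in_law,father,m
grandparent,child_in_law,mother,f
grandparent,child_in_law,aunt_uncle,any
spouse_partner,father,parent_in_law,m
spouse_partner,mother,parent_in_law,f
spouse_partner,sibling,sibling_in_law,any
spouse_partner,grandparent,other,any
spouse_partner,aunt_uncle,other,any
spouse_partner,godparent,other,any
spouse_partner,cousin,other,any
spouse_partner,child,child,any
spouse_partner,niece_nephew,niece_nephew,any
spouse_partner,grandchild,grandchild,any
spouse_partner,spouse_partner,ego,any
spouse_partner,parent_in_law,father,m
spouse_partner,parent_in_law,mother,f
spouse_partner,sibling_in_law,ego,any
spouse_partner,sibling_in_law,sibling,any
spouse_partner,sibling_in_law,sibling_in_law,any
spouse_partner,child_in_law,child_in_law,any
aunt_uncle,father,grandparent,m
aunt_uncle,mother,grandparent,f
aunt_uncle,sibling,father,m
aunt_uncle,sibling,mother,f
aunt_uncle,sibling,aunt_uncle,any
aunt_uncle,grandparent,other,any
aunt_uncle,aunt_uncle,grandparent,any
aunt_uncle,godparent,other,any
aunt_uncle,cousin,aunt_uncle,any
aunt_uncle,child,cousin,any
aunt_uncle,niece_nephew,ego,any
aunt_uncle,niece_nephew,sibling,any
aunt_uncle,niece_nephew,cousin,any
aunt_uncle,grandchild,niece_nephew,any
aunt_uncle,spouse_partner,aunt_uncle,any
aunt_uncle,parent_in_law,other,any
aunt_uncle,sibling_in_law,aunt_uncle,any
aunt_uncle,child_in_law,other,any
cousin,father,aunt_uncle,m
cousin,mother,aunt_uncle,f
cousin,sibling,cousin,any
cousin,grandparent,grandparent,any
cousin,aunt_uncle,father,m
cousin,aunt_uncle,mother,f
cousin,aunt_uncle,aunt_uncle,any
cousin,godparent,other,any
cousin,cousin,ego,any
cousin,cousin,sibling,any
cousin,cousin,cousin,any
cousin,child,niece_nephew,any
cousin,niece_nephew,niece_nephew,any
cousin,grandchild,other,any
cousin,spouse_partner,other,any
cousin,parent_in_law,other,any
cousin,sibling_in_law,other,any
cousin,child_in_law,other,any
child,father,ego,m
child,father,spouse_partner,m
child,mother,ego,f
child,mother,spouse_partner,f
child,sibling,child,any
child,grandparent,father,m
child,grandparent,mother,f
child,grandparent,parent_in_law,any
child,aunt_uncle,sibling,any
child,aunt_uncle,sibling_in_law,any
child,godparent,other,any
child,cousin,niece_nephew,any
child,child,grandchild,any
child,niece_nephew,grandchild,any
child,grandchild,other,any
child,spouse_partner,child_in_law,any
child,parent_in_law,ego,any
child,parent_in_law,spouse_partner,any
child,sibling_in_law,child_in_law,any
child,child_in_law,other,any
parent_in_law,father,other,any
parent_in_law,mother,other,any
parent_in_law,sibling,other,any
parent_in_law,grandparent,other,any
parent_in_law,aunt_uncle,other,any
parent_in_law,godparent,other,any
parent_in_law,cousin,other,any
parent_in_law,child,spouse_partner,any
parent_in_law,child,sibling_in_law,any
parent_in_law,niece_nephew,other,any
parent_in_law,grandchild,child,any
parent_in_law,grandchild,niece_nephew,any
parent_in_law,spouse_partner,parent_in_law,any
parent_in_law,parent_in_law,other,any
parent_in_law,sibling_in_law,other,any
parent_in_law,child_in_law,ego,any
parent_in_law,child_in_law,sibling_in_law,any
sibling_in_law,father,parent_in_law,m
sibling_in_law,father,other,any
sibling_in_law,mother,parent_in_law,f
sibling_in_law,mother,other,any
sibling_in_law,sibling,spouse_partner,any
sibling_in_law,sibling,sibling_in_law,any
sibling_in_law,grandparent,other,any
sibling_in_law,aunt_uncle,other,any
sibling_in_law,godparent,other,any
sibling_in_law,cousin,other,any
sibling_in_law,child,niece_nephew,any
sibling_in_law,niece_nephew,other,any
sibling_in_law,grandchild,other,any
sibling_in_law,spouse_partner,sibling,any
sibling_in_law,spouse_partner,sibling_in_law,any
sibling_in_law,parent_in_law,other,any
sibling_in_law,sibling_in_law,other,any
sibling_in_law,child_in_law,other,any
godparent,child,other,any
godparent,spouse_partner,godparent,any
godparent,godchild,ego,any
godparent,godchild,sibling,any
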